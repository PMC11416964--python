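"""Genotype and phenotype containers, file I/O, marker filtering and in-silico hybrids.

Dosages are coded as the count of the alternate allele (0/1/2) with ``numpy.nan``
for missing calls. Inbred parents are expected to be (nearly) homozygous, so an
F1 hybrid genotype is deterministic: the mean of the two parental dosages on the
same 0-2 scale, which for fully inbred parents equals the true F1 dosage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class GenotypeError(ValueError):
    """Malformed or inconsistent genotype data."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for x in ids:
            if x in seen:
                raise GenotypeError(f"duplicate {what}: {x!r}")
            seen.add(x)


@dataclass
class GenotypeMatrix:
    """Lines x markers alt-allele dosage matrix.

    Parameters
    ----------
    line_ids : ordered unique line names.
    marker_ids : ordered unique marker names.
    dosages : float array, shape (n_lines, n_markers); entries in {0, 1, 2} or NaN.
    chrom, pos, ref, alt : optional per-marker metadata (pos is 1-based).
    """

    line_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    chrom: list[str] | None = None
    pos: np.ndarray | None = None
    ref: list[str] | None = None
    alt: list[str] | None = None
    # imputation produces fractional dosages; set False after impute_missing
    strict_classes: bool = True

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.line_ids), len(self.marker_ids)):
            raise GenotypeError(
                f"dosage shape {self.dosages.shape} != "
                f"({len(self.line_ids)}, {len(self.marker_ids)})"
            )
        _check_unique(self.line_ids, "line id")
        _check_unique(self.marker_ids, "marker id")
        observed = self.dosages[~np.isnan(self.dosages)]
        if self.strict_classes:
            if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
                bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))][0]
                raise GenotypeError(f"dosage value {bad!r} not in {{0,1,2,NaN}}")
        elif observed.size and (observed.min() < 0 or observed.max() > 2):
            raise GenotypeError("dosage outside [0, 2]")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset_markers(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            marker_ids=[self.marker_ids[j] for j in keep],
            dosages=self.dosages[:, keep].copy(),
            chrom=[self.chrom[j] for j in keep] if self.chrom else None,
            pos=self.pos[keep].copy() if self.pos is not None else None,
            ref=[self.ref[j] for j in keep] if self.ref else None,
            alt=[self.alt[j] for j in keep] if self.alt else None,
            strict_classes=self.strict_classes,
        )

    def row(self, line_id: str) -> np.ndarray:
        return self.dosages[self.line_ids.index(line_id)]


@dataclass
class HybridGenotypeMatrix:
    """In-silico hybrid genotypes: mean of the two parental dosage rows.

    ``hybrid_ids`` are canonical "p1 x p2" with the lexicographically smaller
    parent first; the matrix is therefore symmetric in the parent order.
    """

    hybrid_ids: list[str]
    parents: list[tuple[str, str]]
    marker_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        _check_unique(self.hybrid_ids, "hybrid id")
        if self.dosages.shape != (len(self.hybrid_ids), len(self.marker_ids)):
            raise GenotypeError("hybrid dosage shape mismatch")

    @property
    def n_hybrids(self) -> int:
        return len(self.hybrid_ids)


def canonical_cross(p1: str, p2: str) -> tuple[str, str]:
    """Unordered pair in canonical (lexicographic) order."""
    return (p1, p2) if p1 <= p2 else (p2, p1)


def hybrid_name(p1: str, p2: str) -> str:
    a, b = canonical_cross(p1, p2)
    return f"{a}x{b}"


@dataclass
class PhenotypeTable:
    """Hybrid phenotype records: parent pair plus one column per trait."""

    data: pd.DataFrame  # columns: hybrid_id, parent1, parent2, <traits...>

    RESERVED = ("hybrid_id", "parent1", "parent2")

    def __post_init__(self) -> None:
        for col in self.RESERVED:
            if col not in self.data.columns:
                raise GenotypeError(f"phenotype table missing column {col!r}")
        if (self.data["parent1"] == self.data["parent2"]).any():
            raise GenotypeError("self-cross in phenotype table")
        pairs = [canonical_cross(a, b) for a, b in
                 zip(self.data["parent1"], self.data["parent2"])]
        if len(set(pairs)) != len(pairs):
            raise GenotypeError("duplicate parent pair in phenotype table")

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.RESERVED]

    @property
    def hybrid_ids(self) -> list[str]:
        return list(self.data["hybrid_id"])

    def trait_values(self, trait: str) -> pd.Series:
        return self.data.set_index("hybrid_id")[trait]

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, dtype={"hybrid_id": str,
                                            "parent1": str, "parent2": str}))


@dataclass
class FilterReport:
    """Accounting of the three marker-retention criteria.

    Drop attribution is first-failing in the order: (a) fewer than two genotype
    classes, (b) missing fraction above threshold, (c) rare-allele frequency
    below threshold; so n_input = n_kept + sum(drops).
    """

    n_input_markers: int
    n_kept: int
    dropped_monomorphic: int
    dropped_missing: int
    dropped_rare_allele: int
    kept_marker_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


# ---------------------------------------------------------------------------
# Reading / writing

def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF (biallelic, GT field) or TSV dosage file.

    Format is inferred from the suffix when not given. Multi-allelic VCF
    records are skipped (counted, not fatal); missing GT maps to NaN.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz") else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    _check_unique(line_ids, "line id")
    marker_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    cols: list[np.ndarray] = []
    n_multiallelic = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multiallelic += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        g = np.asarray(var.gt_types, dtype=float)
        dos = np.where(g == 0, 0.0, np.where(g == 1, 1.0,
                       np.where(g == 3, 2.0, np.nan)))
        cols.append(dos)
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
    if not cols:
        raise GenotypeError(f"no biallelic records in {path}")
    gm = GenotypeMatrix(line_ids, marker_ids, np.column_stack(cols),
                        chrom=chrom, pos=np.asarray(pos), ref=ref, alt=alt)
    gm.n_multiallelic_skipped = n_multiallelic  # type: ignore[attr-defined]
    return gm


def _read_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        line_ids=[str(i) for i in df.index],
        marker_ids=[str(c) for c in df.columns],
        dosages=df.to_numpy(dtype=float),
    )


def write_genotypes(g: GenotypeMatrix, path: str | Path,
                    format: str | None = None) -> None:
    """Write as VCF (GT field, unphased) or TSV dosage matrix."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" else "tsv"
    if format == "tsv":
        pd.DataFrame(g.dosages, index=g.line_ids, columns=g.marker_ids).to_csv(
            path, sep="\t", index_label="line_id")
        return
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = g.chrom or ["1"] * g.n_markers
        for c in dict.fromkeys(chroms):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.line_ids) + "\n")
        pos = g.pos if g.pos is not None else np.arange(1, g.n_markers + 1)
        ref = g.ref or ["A"] * g.n_markers
        alt = g.alt or ["T"] * g.n_markers
        for j in range(g.n_markers):
            calls = "\t".join(
                "./." if np.isnan(d) else gt_of[d] for d in g.dosages[:, j])
            fh.write(f"{chroms[j]}\t{int(pos[j])}\t{g.marker_ids[j]}\t"
                     f"{ref[j]}\t{alt[j]}\t.\t.\t.\tGT\t{calls}\n")


# ---------------------------------------------------------------------------
# Marker filtering

def filter_hybrid_markers(
    g: GenotypeMatrix,
    max_missing: float = 0.3,
    min_rare_allele: float = 0.1,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the three marker-retention criteria, in order, per locus.

    A marker is kept iff (a) it shows at least two distinct non-missing
    genotype classes, (b) its missing fraction is <= ``max_missing``, and
    (c) its minor-allele frequency over non-missing calls is >= ``min_rare_allele``.
    Drop counts attribute each dropped marker to the first failing criterion.
    """
    if g.n_markers == 0:
        raise GenotypeError("empty genotype matrix")
    D = g.dosages
    obs = ~np.isnan(D)
    n_lines = D.shape[0]
    n_obs = obs.sum(axis=0)

    n_classes = np.zeros(g.n_markers, dtype=int)
    for cls in (0.0, 1.0, 2.0):
        n_classes += ((D == cls).sum(axis=0) > 0).astype(int)
    fail_a = n_classes < 2

    miss_frac = 1.0 - n_obs / n_lines
    fail_b = miss_frac > max_missing

    with np.errstate(invalid="ignore"):
        p_alt = np.nansum(D, axis=0) / (2.0 * np.maximum(n_obs, 1))
    maf = np.minimum(p_alt, 1.0 - p_alt)
    fail_c = maf < min_rare_allele

    drop_a = fail_a
    drop_b = fail_b & ~drop_a
    drop_c = fail_c & ~drop_a & ~drop_b
    keep = ~(drop_a | drop_b | drop_c)
    keep_idx = np.flatnonzero(keep)

    report = FilterReport(
        n_input_markers=g.n_markers,
        n_kept=int(keep.sum()),
        dropped_monomorphic=int(drop_a.sum()),
        dropped_missing=int(drop_b.sum()),
        dropped_rare_allele=int(drop_c.sum()),
        kept_marker_ids=[g.marker_ids[j] for j in keep_idx],
    )
    if report.n_kept == 0:
        import warnings

        warnings.warn("all markers dropped by filtering", stacklevel=2)
    return g.subset_markers(keep_idx), report


# ---------------------------------------------------------------------------
# Hybrids and imputation

def make_hybrid_genotypes(
    parents: GenotypeMatrix,
    crosses: Iterable[tuple[str, str]],
) -> HybridGenotypeMatrix:
    """Construct F1 dosages as the parental mean; missing if either parent is.

    Self-crosses are rejected (the half-diallel excludes them); the hybrid id
    puts the lexicographically smaller parent first, so (A,B) and (B,A) give
    identical rows.
    """
    index = {lid: i for i, lid in enumerate(parents.line_ids)}
    pairs: list[tuple[str, str]] = []
    for p1, p2 in crosses:
        if p1 == p2:
            raise GenotypeError(f"self-cross {p1!r} x {p2!r} not allowed")
        for p in (p1, p2):
            if p not in index:
                raise GenotypeError(f"unknown parent {p!r}")
        pairs.append(canonical_cross(p1, p2))
    rows = np.empty((len(pairs), parents.n_markers))
    for k, (a, b) in enumerate(pairs):
        rows[k] = (parents.dosages[index[a]] + parents.dosages[index[b]]) / 2.0
    return HybridGenotypeMatrix(
        hybrid_ids=[f"{a}x{b}" for a, b in pairs],
        parents=pairs,
        marker_ids=list(parents.marker_ids),
        dosages=rows,
    )


def impute_missing(g):
    """Replace missing entries with the marker (column) mean of observed calls.

    Works for both parental and hybrid matrices; errors on a fully-missing
    marker (filter first). Observed entries are untouched, so column means
    over observed calls are preserved exactly.
    """
    D = g.dosages
    obs = ~np.isnan(D)
    if not obs.any(axis=0).all():
        j = int(np.flatnonzero(~obs.any(axis=0))[0])
        raise GenotypeError(
            f"marker {g.marker_ids[j]!r} fully missing; run filter_hybrid_markers first")
    col_means = np.nansum(D, axis=0) / obs.sum(axis=0)
    filled = np.where(obs, D, col_means[None, :])
    if isinstance(g, HybridGenotypeMatrix):
        return HybridGenotypeMatrix(list(g.hybrid_ids), list(g.parents),
                                    list(g.marker_ids), filled)
    return GenotypeMatrix(
        line_ids=list(g.line_ids),
        marker_ids=list(g.marker_ids),
        dosages=filled,
        chrom=list(g.chrom) if g.chrom else None,
        pos=g.pos.copy() if g.pos is not None else None,
        ref=list(g.ref) if g.ref else None,
        alt=list(g.alt) if g.alt else None,
        strict_classes=False,
    )
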