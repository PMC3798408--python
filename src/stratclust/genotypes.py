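"""Genotype data model, file I/O, allele frequencies, recoding and standardisation.

Genotypes are coded per marker as minor-allele counts: 0 for homozygotes of
the frequent allele, 1 for heterozygotes, 2 for homozygotes of the rare
allele.  Missing calls are carried as ``NaN`` in a float matrix so that every
downstream step (distances, projection, likelihoods) can apply its own
available-case rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID_CELLS = {"0", "1", "2", "NA", ""}

__all__ = [
    "GenotypeMatrix",
    "MarkerStats",
    "StandardizedMatrix",
    "SampleTable",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_vcf",
    "estimate_allele_freq",
    "recode_to_minor",
    "standardize",
]


class GenotypeParseError(ValueError):
    """A cell of a genotype file is outside {0, 1, 2, NA, empty}."""


class GenotypeValidationError(ValueError):
    """A genotype container violates its invariants (codes, IDs, shape)."""


@dataclass
class GenotypeMatrix:
    """A sample x marker table of genotype codes.

    Parameters
    ----------
    sample_ids, marker_ids
        Unique row / column identifiers.
    values
        Float array of shape ``(n, m)`` with entries in {0, 1, 2} or NaN
        for missing calls.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.marker_ids = [str(s) for s in self.marker_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GenotypeValidationError("values must be a 2-D array")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise GenotypeValidationError("need at least one sample and one marker")
        if len(self.sample_ids) != n or len(self.marker_ids) != m:
            raise GenotypeValidationError("ID lists do not match the value grid shape")
        if len(set(self.sample_ids)) != n:
            raise GenotypeValidationError("duplicate sample IDs")
        if len(set(self.marker_ids)) != m:
            raise GenotypeValidationError("duplicate marker IDs")
        observed = self.values[~np.isnan(self.values)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))]
            raise GenotypeValidationError(
                f"non-genotype codes present (first offending value: {bad[0]!r})"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, m)`` array, True where the call is missing."""
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.marker_ids)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to markers selected by boolean mask or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.sample_ids,
            [self.marker_ids[j] for j in keep],
            self.values[:, keep].copy(),
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in keep],
            self.marker_ids,
            self.values[keep, :].copy(),
        )


@dataclass
class MarkerStats:
    """Per-marker frequency summaries.

    ``freq`` is the counted-allele frequency in the matrix's current
    orientation; ``maf`` folds it to the minor allele, so ``maf <= 0.5``.
    """

    freq: np.ndarray
    maf: np.ndarray
    call_rate: np.ndarray
    n_obs: np.ndarray


@dataclass
class StandardizedMatrix:
    """Standardised genotypes with missing entries replaced by zero.

    ``values[i, j] = (g_ij - 2 p_j) / sqrt(2 p_j (1 - p_j))`` for observed
    calls; exactly 0 where the source call was missing, with the original
    missingness kept in ``source_missing_mask``.
    """

    values: np.ndarray
    source_missing_mask: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    marker_ids: list[str] = field(default_factory=list)
    freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.source_missing_mask = np.asarray(self.source_missing_mask, dtype=bool)
        if self.values.shape != self.source_missing_mask.shape:
            raise GenotypeValidationError("values / mask shape mismatch")
        if not np.isfinite(self.values).all():
            raise GenotypeValidationError("standardised values must be finite")
        if self.values[self.source_missing_mask].size and np.any(
            self.values[self.source_missing_mask] != 0.0
        ):
            raise GenotypeValidationError("missing positions must be exactly zero")


class SampleTable:
    """Categorical per-sample metadata (population label, subphenotypes).

    A thin wrapper over a :class:`pandas.DataFrame` indexed by sample ID;
    alignment with a :class:`GenotypeMatrix` is always by ID, never by order.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            raise GenotypeValidationError("duplicate sample IDs in metadata")
        self.frame = frame.copy()
        self.frame.index = self.frame.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def column(self, name: str, sample_ids: list[str] | None = None) -> pd.Series:
        """A categorical column, optionally re-indexed to ``sample_ids``."""
        col = self.frame[name]
        if sample_ids is not None:
            col = col.reindex([str(s) for s in sample_ids])
        return col

    @classmethod
    def read_tsv(cls, path) -> "SampleTable":
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                            keep_default_na=False)
        frame = frame.replace({"NA": None, "": None})
        return cls(frame)

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    """Read a genotype TSV: one header row of marker IDs, first column sample IDs.

    Cells must be ``0``, ``1``, ``2``, ``NA`` or empty (missing).  Row and
    column order are preserved.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                        keep_default_na=False)
    values = np.full(frame.shape, np.nan)
    raw = frame.to_numpy()
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            cell = raw[i, j].strip()
            if cell not in _VALID_CELLS:
                raise GenotypeParseError(
                    f"invalid genotype {cell!r} at sample {frame.index[i]!r}, "
                    f"marker {frame.columns[j]!r}"
                )
            if cell in ("0", "1", "2"):
                values[i, j] = float(cell)
    return GenotypeMatrix(list(frame.index), list(frame.columns), values)


def write_genotypes_tsv(G: GenotypeMatrix, path) -> None:
    """Write the same dialect :func:`read_genotypes_tsv` consumes (NA = missing)."""
    frame = G.to_frame()
    out = frame.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_vcf(path, sample_subset: list[str] | None = None) -> GenotypeMatrix:
    """Import biallelic sites from a VCF, counting the ALT allele.

    GT "0/0" -> 0, "0/1"/"1/0" -> 1, "1/1" -> 2, "./." -> missing.
    Non-biallelic records are skipped (count logged).  The ALT allele is not
    necessarily the minor allele; run :func:`recode_to_minor` afterwards.
    """
    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    vcf = VCF(str(path), gts012=True)
    if sample_subset is not None:
        missing = set(sample_subset) - set(vcf.samples)
        if missing:
            raise GenotypeValidationError(f"samples absent from VCF: {sorted(missing)}")
        vcf.set_samples(sample_subset)
    samples = list(vcf.samples)

    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        if "GT" not in variant.FORMAT:
            raise GenotypeParseError(f"record {variant.ID or variant.POS} lacks GT")
        # gts012: 0/1/2 = ALT allele count, 3 = missing
        codes = np.asarray(variant.gt_types, dtype=float)
        codes[codes == 3] = np.nan
        marker_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        rows.append(codes)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic records", n_skipped)
    if not rows:
        raise GenotypeValidationError("no biallelic records with genotypes in VCF")
    G = GenotypeMatrix(samples, marker_ids, np.column_stack(rows))
    G.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return G


def estimate_allele_freq(G: GenotypeMatrix) -> MarkerStats:
    """Available-case allele frequency per marker.

    freq_j = (sum of observed codes) / (2 * n_obs_j) — the frequency of the
    counted allele in the matrix's current orientation.
    """
    obs = ~G.missing_mask
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        bad = [G.marker_ids[j] for j in np.flatnonzero(n_obs == 0)]
        raise GenotypeValidationError(f"markers with no observed calls: {bad}")
    totals = np.nansum(G.values, axis=0)
    freq = totals / (2.0 * n_obs)
    maf = np.minimum(freq, 1.0 - freq)
    return MarkerStats(freq=freq, maf=maf, call_rate=n_obs / G.n, n_obs=n_obs)


def recode_to_minor(G: GenotypeMatrix) -> tuple[GenotypeMatrix, np.ndarray]:
    """Flip markers whose counted-allele frequency exceeds 0.5 (g -> 2 - g).

    Ties at exactly 0.5 keep the original orientation so the operation is
    deterministic.  Returns the recoded matrix and the boolean flip log.
    """
    stats = estimate_allele_freq(G)
    flipped = stats.freq > 0.5
    values = G.values.copy()
    values[:, flipped] = 2.0 - values[:, flipped]
    return GenotypeMatrix(G.sample_ids, G.marker_ids, values), flipped


def standardize(G: GenotypeMatrix, stats: MarkerStats | None = None) -> StandardizedMatrix:
    """Centre and scale each marker column; zero-fill missing calls.

    s_ij = (g_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)) with p_j the estimated
    allele frequency of marker j (available-case, from ``stats`` or from G
    itself).  Monomorphic markers (p_j in {0, 1}) are rejected: the
    denominator is undefined and they carry no information — filter them
    first.
    """
    if stats is None:
        stats = estimate_allele_freq(G)
    p = np.asarray(stats.freq, dtype=float)
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        bad = [G.marker_ids[j] for j in np.flatnonzero(mono)]
        raise GenotypeValidationError(
            f"monomorphic markers must be excluded before standardisation: {bad}"
        )
    mask = G.missing_mask
    values = (G.values - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    values[mask] = 0.0
    return StandardizedMatrix(
        values=values,
        source_missing_mask=mask,
        sample_ids=list(G.sample_ids),
        marker_ids=list(G.marker_ids),
        freqs=p,
    )


def drop_monomorphic(G: GenotypeMatrix) -> tuple[GenotypeMatrix, list[str]]:
    """Remove markers with available-case frequency 0 or 1, logging a warning."""
    stats = estimate_allele_freq(G)
    mono = (stats.freq <= 0.0) | (stats.freq >= 1.0)
    dropped = [G.marker_ids[j] for j in np.flatnonzero(mono)]
    if dropped:
        logger.warning("dropping %d monomorphic markers: %s", len(dropped), dropped)
        G = G.subset_markers(~mono)
    return G, dropped
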