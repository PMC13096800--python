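"""Identification filtering, normalization, imputation, and iBAQ conversion.

These are the standard preparation steps applied to a :class:`QuantMatrix`
before kinetics or differential analysis:

* removal of reverse/contaminant identifications and weakly supported
  proteins (peptide / precursor / spectral-count thresholds),
* median-centering against a reference set (typically the glycoprotein
  background that is enriched independently of crosslinking),
* left-censored missing-value imputation from a down-shifted normal
  distribution (Perseus-style parameters: width as a fraction of the
  per-sample sd, downshift in per-sample sd units),
* LFQ -> normalized iBAQ conversion via an in-silico tryptic digest,
* pseudocounting for enrichment-ratio display.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .containers import QuantMatrix

__all__ = [
    "FilterParams",
    "ImputeParams",
    "filter_identifications",
    "median_center",
    "impute_missing",
    "count_observable_peptides",
    "lfq_to_ibaq",
    "add_pseudocount",
]


@dataclass(frozen=True)
class FilterParams:
    """Identification-filter thresholds; 0 disables a count rule."""

    min_peptides: int = 0
    min_precursors: int = 0
    min_max_spectral_count: int = 0
    drop_contaminants: bool = True
    drop_reverse: bool = True

    def __post_init__(self) -> None:
        for name in ("min_peptides", "min_precursors", "min_max_spectral_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ImputeParams:
    """Down-shifted normal imputation parameters (per-sample sd units)."""

    width: float = 0.3
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")


class ConfigurationError(ValueError):
    """A threshold is active but the required evidence column is absent."""


# fixed application order keeps removal reports deterministic
_RULE_ORDER = ("reverse", "contaminant", "peptides", "precursors",
               "spectral_counts")


def filter_identifications(
    qm: QuantMatrix, params: FilterParams
) -> QuantMatrix:
    """Apply the identification filters; attaches a removal report.

    The returned matrix contains exactly the rows passing every active rule,
    in input order. The per-rule removal counts (rule applied sequentially in
    the fixed order reverse -> contaminant -> peptides -> precursors ->
    spectral counts) are appended to the matrix ``log``.
    """
    keep = np.ones(qm.n_proteins, dtype=bool)
    report: dict[str, int] = {}

    def _evidence(column: str) -> np.ndarray:
        if qm.evidence is None or column not in qm.evidence.columns:
            raise ConfigurationError(
                f"filter threshold on {column!r} active but evidence column "
                "is absent"
            )
        return qm.evidence[column].fillna(0).to_numpy()

    for rule in _RULE_ORDER:
        if rule == "reverse" and params.drop_reverse:
            fail = qm.flags["reverse"].to_numpy()
        elif rule == "contaminant" and params.drop_contaminants:
            fail = qm.flags["contaminant"].to_numpy()
        elif rule == "peptides" and params.min_peptides > 0:
            fail = _evidence("peptides") < params.min_peptides
        elif rule == "precursors" and params.min_precursors > 0:
            fail = _evidence("precursors") < params.min_precursors
        elif rule == "spectral_counts" and params.min_max_spectral_count > 0:
            fail = _evidence("spectral_counts") < params.min_max_spectral_count
        else:
            continue
        newly = fail & keep
        report[rule] = int(newly.sum())
        keep &= ~fail

    out = qm.select_proteins(keep)
    out.log.append(
        "filter_identifications: "
        + ", ".join(f"{k} removed {v}" for k, v in report.items())
    )
    out.removal_report = report  # type: ignore[attr-defined]
    return out


def median_center(
    qm: QuantMatrix, reference: set[str] | None = None
) -> QuantMatrix:
    """Scale each sample so reference medians agree across samples.

    Each sample's intensities are multiplied by a scalar such that the median
    of the reference proteins' non-missing intensities becomes identical in
    every sample; the common target is the across-sample geometric mean of the
    pre-centering reference medians (symmetric in sample order and
    scale-preserving). ``reference=None`` centers on all proteins.
    """
    if reference is None:
        mask = np.ones(qm.n_proteins, dtype=bool)
    else:
        mask = np.array([p in reference for p in qm.protein_ids])
        if not mask.any():
            raise ValueError("reference set matches no protein in the matrix")
    medians = np.empty(qm.n_samples)
    for j in range(qm.n_samples):
        vals = qm.intensities[mask, j]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(
                f"sample {qm.samples[j].sample_id!r} has no finite reference "
                "intensity"
            )
        medians[j] = np.median(vals)
    if np.any(medians <= 0):
        bad = qm.samples[int(np.argmin(medians))].sample_id
        raise ValueError(f"non-positive reference median in sample {bad!r}")
    target = math.exp(float(np.mean(np.log(medians))))
    scale = target / medians
    out = qm.with_intensities(qm.intensities * scale[np.newaxis, :])
    out.log.append(f"median_center: target median {target:.6g}")
    return out


def impute_missing(qm: QuantMatrix, params: ImputeParams) -> QuantMatrix:
    """Impute missing values from a down-shifted normal, per sample.

    For each sample, let mu and sigma be the mean and sd (ddof=1) of the
    observed natural-log intensities; every missing entry is replaced by
    ``exp(x)`` with ``x ~ Normal(mu - downshift*sigma, (width*sigma)^2)``.
    Observed values are untouched; draws are reproducible from ``params.seed``.
    """
    values = qm.intensities.copy()
    rng = np.random.default_rng(params.seed)
    for j in range(qm.n_samples):
        col = values[:, j]
        observed = np.isfinite(col)
        if observed.sum() < 2:
            raise ValueError(
                f"sample {qm.samples[j].sample_id!r} has fewer than 2 "
                "observed values; sd undefined"
            )
        if np.any(col[observed] <= 0):
            raise ValueError("intensities must be > 0 for log imputation")
        logs = np.log(col[observed])
        mu = float(np.mean(logs))
        sigma = float(np.std(logs, ddof=1))
        n_missing = int((~observed).sum())
        if n_missing:
            draws = rng.normal(
                mu - params.downshift * sigma,
                params.width * sigma,
                size=n_missing,
            )
            col[~observed] = np.exp(draws)
    out = qm.with_intensities(values)
    out.log.append(
        f"impute_missing: width={params.width} downshift={params.downshift} "
        f"seed={params.seed}"
    )
    return out


def count_observable_peptides(
    sequence: str, min_len: int = 7, max_len: int = 30
) -> int:
    """Count theoretically observable tryptic peptides.

    Cleavage after K/R except before P, zero missed cleavages; a fragment of
    length 7-30 residues (inclusive) counts as observable.
    """
    peptides = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in "KR" and not (i + 1 < len(sequence) and sequence[i + 1] == "P"):
            peptides.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        peptides.append(sequence[start:])
    return sum(min_len <= len(p) <= max_len for p in peptides)


def lfq_to_ibaq(
    qm: QuantMatrix, sequences: Mapping[str, str]
) -> QuantMatrix:
    """Convert LFQ intensities to normalized iBAQ.

    Each protein's intensity is divided by its count of theoretically
    observable tryptic peptides; each sample is then rescaled to sum to 1.
    Proteins without a sequence or with zero observable peptides are excluded
    with a warning.
    """
    counts = np.zeros(qm.n_proteins)
    for i, pid in enumerate(qm.protein_ids):
        lead = pid.split(";")[0]
        seq = sequences.get(pid, sequences.get(lead))
        if seq:
            counts[i] = count_observable_peptides(seq)
    keep = counts > 0
    dropped = [p for p, k in zip(qm.protein_ids, keep) if not k]
    if dropped:
        warnings.warn(
            f"lfq_to_ibaq: excluded {len(dropped)} protein(s) with no "
            f"observable peptides: {dropped[:5]}{'...' if len(dropped) > 5 else ''}"
        )
    out = qm.select_proteins(keep)
    ibaq = out.intensities / counts[keep, np.newaxis]
    sums = np.nansum(ibaq, axis=0)
    if np.any(sums <= 0):
        raise ValueError("a sample has no finite intensity after conversion")
    out = out.with_intensities(ibaq / sums[np.newaxis, :])
    out.log.append(
        "lfq_to_ibaq: tryptic digest, 0 missed cleavages, observable length "
        f"7-30; excluded {len(dropped)} proteins"
    )
    return out


def add_pseudocount(
    qm: QuantMatrix, value: float | str = "auto"
) -> QuantMatrix:
    """Add a pseudocount to every entry (missing treated as 0 first).

    ``value="auto"`` uses the smallest nonzero intensity in the matrix. Makes
    enrichment ratios of proteins absent in a reference sample finite.
    """
    if value == "auto":
        finite = qm.intensities[np.isfinite(qm.intensities)]
        finite = finite[finite > 0]
        if finite.size == 0:
            raise ValueError("matrix has no nonzero intensity for auto pseudocount")
        value = float(finite.min())
    value = float(value)
    if value <= 0:
        raise ValueError("pseudocount must be > 0")
    filled = np.nan_to_num(qm.intensities, nan=0.0) + value
    out = qm.with_intensities(filled)
    out.log.append(f"add_pseudocount: {value:.6g}")
    return out
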