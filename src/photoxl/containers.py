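"""Core in-memory containers shared across the pipeline.

The central object is :class:`QuantMatrix`, a proteins x samples intensity
table with per-sample metadata and per-protein evidence/flags, mirroring the
information content of a MaxQuant ``proteinGroups`` table or a DIA-NN
``pg_matrix`` plus a sidecar sample sheet. Missing measurements are stored as
``NaN``; raw zeros are converted to missing on read because downstream log
transforms and imputation require an explicit missing state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "SampleMeta",
    "QuantMatrix",
    "CrosslinkPair",
    "StructureModel",
]

VALID_SOURCES = ("bulb", "led", "none")


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one quantification run.

    Parameters
    ----------
    sample_id
        Run name, matching the intensity column it came from.
    condition
        Experimental condition label (cell line, drug, irradiation source ...).
    irradiation_time
        Irradiation duration in seconds; 0 iff ``irradiation_source`` is
        ``"none"``.
    irradiation_source
        One of ``"bulb"``, ``"led"``, ``"none"``.
    replicate
        1-based replicate index within the condition.
    batch
        Optional processing-batch label; differential contrasts are restricted
        to within-batch comparisons.
    """

    sample_id: str
    condition: str = ""
    irradiation_time: float = 0.0
    irradiation_source: str = "none"
    replicate: int = 1
    batch: str = ""

    def __post_init__(self) -> None:
        if self.irradiation_source not in VALID_SOURCES:
            raise ValueError(
                f"irradiation_source must be one of {VALID_SOURCES}, "
                f"got {self.irradiation_source!r}"
            )
        if self.irradiation_time < 0:
            raise ValueError("irradiation_time must be >= 0")
        if (self.irradiation_time == 0) != (self.irradiation_source == "none"):
            raise ValueError(
                f"sample {self.sample_id!r}: irradiation_time == 0 iff "
                "irradiation_source == 'none'"
            )
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


EVIDENCE_COLUMNS = ("peptides", "precursors", "spectral_counts")
FLAG_COLUMNS = ("contaminant", "reverse", "glycoprotein")


@dataclass
class QuantMatrix:
    """Proteins x samples intensity matrix with metadata.

    ``intensities`` is a float array of shape ``(n_proteins, n_samples)`` with
    ``NaN`` marking missing values. Raw intensity matrices are non-negative
    (enforced by the readers); matrices may also carry log-scale values, e.g.
    as input to the moderated t test. ``evidence`` holds optional integer identification-evidence counts
    (columns: ``peptides``, ``precursors``, ``spectral_counts``) and ``flags``
    per-protein booleans (``contaminant``, ``reverse``, ``glycoprotein``).
    """

    protein_ids: list[str]
    intensities: np.ndarray
    samples: list[SampleMeta]
    evidence: pd.DataFrame | None = None
    flags: pd.DataFrame | None = None
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D array")
        n_prot, n_samp = self.intensities.shape
        if len(self.protein_ids) != n_prot:
            raise ValueError("protein_ids length does not match intensity rows")
        if len(self.samples) != n_samp:
            raise ValueError("sample metadata count does not match columns")
        if len(set(self.protein_ids)) != n_prot:
            raise ValueError("protein ids must be unique within a matrix")
        keys = [
            (s.condition, s.irradiation_time, s.replicate) for s in self.samples
        ]
        if len(set(keys)) != len(keys):
            raise ValueError(
                "(condition, irradiation_time, replicate) must be unique"
            )
        if self.flags is None:
            self.flags = pd.DataFrame(
                False, index=self.protein_ids, columns=list(FLAG_COLUMNS)
            )
        else:
            self.flags = self.flags.reindex(
                index=self.protein_ids, columns=list(FLAG_COLUMNS),
                fill_value=False,
            ).astype(bool)
        if self.evidence is not None:
            self.evidence = self.evidence.reindex(index=self.protein_ids)

    # -- basic accessors -------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        """Intensity matrix as a DataFrame (proteins x sample ids)."""
        return pd.DataFrame(
            self.intensities, index=self.protein_ids, columns=self.sample_ids
        )

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(
            protein_ids=list(self.protein_ids),
            intensities=self.intensities.copy(),
            samples=list(self.samples),
            evidence=None if self.evidence is None else self.evidence.copy(),
            flags=self.flags.copy(),
            log=list(self.log),
        )

    def select_proteins(self, keep: Sequence[bool] | np.ndarray) -> "QuantMatrix":
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (self.n_proteins,):
            raise ValueError("protein mask has wrong length")
        ids = [p for p, k in zip(self.protein_ids, keep) if k]
        return QuantMatrix(
            protein_ids=ids,
            intensities=self.intensities[keep],
            samples=list(self.samples),
            evidence=None if self.evidence is None else self.evidence.loc[ids],
            flags=self.flags.loc[ids],
            log=list(self.log),
        )

    def select_samples(self, idx: Sequence[int]) -> "QuantMatrix":
        idx = list(idx)
        return QuantMatrix(
            protein_ids=list(self.protein_ids),
            intensities=self.intensities[:, idx],
            samples=[self.samples[i] for i in idx],
            evidence=None if self.evidence is None else self.evidence.copy(),
            flags=self.flags.copy(),
            log=list(self.log),
        )

    def samples_for(self, condition: str) -> list[int]:
        """Column indices belonging to a condition label."""
        return [i for i, s in enumerate(self.samples) if s.condition == condition]

    def with_intensities(self, values: np.ndarray) -> "QuantMatrix":
        out = self.copy()
        out.intensities = np.asarray(values, dtype=float)
        if out.intensities.shape != self.intensities.shape:
            raise ValueError("replacement intensities have wrong shape")
        return out

    def set_glycoproteins(self, accessions: Iterable[str]) -> "QuantMatrix":
        out = self.copy()
        acc = set(accessions)
        out.flags["glycoprotein"] = [p in acc for p in out.protein_ids]
        return out


@dataclass(frozen=True)
class CrosslinkPair:
    """A crosslinked residue pair; identity is unordered."""

    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int
    chain_hint_a: str | None = None
    chain_hint_b: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.residue_a < 1 or self.residue_b < 1:
            raise ValueError("residue positions are 1-based and must be >= 1")

    def _key(self) -> tuple:
        ends = sorted(
            [
                (self.protein_a, self.residue_a, self.chain_hint_a or ""),
                (self.protein_b, self.residue_b, self.chain_hint_b or ""),
            ]
        )
        return tuple(ends)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CrosslinkPair):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def reversed(self) -> "CrosslinkPair":
        return CrosslinkPair(
            protein_a=self.protein_b,
            residue_a=self.residue_b,
            protein_b=self.protein_a,
            residue_b=self.residue_a,
            chain_hint_a=self.chain_hint_b,
            chain_hint_b=self.chain_hint_a,
            score=self.score,
        )


@dataclass
class StructureModel:
    """Calpha coordinates per chain, keyed by author residue number."""

    chains: dict[str, dict[int, np.ndarray]]

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            for num, xyz in residues.items():
                arr = np.asarray(xyz, dtype=float)
                if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                    raise ValueError(
                        f"chain {cid} residue {num}: Calpha coordinate must be "
                        "a finite 3-vector"
                    )
                residues[num] = arr

    def has_residue(self, chain: str, residue: int) -> bool:
        return chain in self.chains and residue in self.chains[chain]

    def ca(self, chain: str, residue: int) -> np.ndarray:
        return self.chains[chain][residue]

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())
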