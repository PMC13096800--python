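"""Crosslink-to-structure distance validation.

Crosslinked residue pairs are checked against a 3D structure by the Euclidean
distance between the Calpha atoms of the two residues. For homomultimers the
chain assignment of a residue pair is ambiguous; by default each pair is
assigned the chain combination with the minimal distance (the standard
convention for indistinguishable chains), with a fixed-assignment mode
available when chain hints are trusted. A pair is satisfied when its distance
does not exceed the crosslinker-specific limit (30 A for sulfo-SDA);
records exactly at the limit are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CrosslinkPair, StructureModel

__all__ = [
    "DistanceRecord",
    "DistanceSummary",
    "ca_distance",
    "resolve_assignment",
    "distance_summary",
    "records_frame",
]

DEFAULT_LIMIT = 30.0
_LIMIT_EPS = 1e-9


@dataclass(frozen=True)
class DistanceRecord:
    """One evaluated crosslink pair."""

    pair: CrosslinkPair
    chain_a: str | None
    chain_b: str | None
    distance: float | None  # Angstrom; None when unmapped
    satisfied: bool | None  # None when unmapped
    at_limit: bool = False

    @property
    def mapped(self) -> bool:
        return self.distance is not None


@dataclass(frozen=True)
class DistanceSummary:
    n_total: int
    n_mapped: int
    n_satisfied: int
    n_at_limit: int
    fraction_satisfied: float | None
    limit: float


def ca_distance(
    model: StructureModel, chain_a: str, res_a: int, chain_b: str, res_b: int
) -> float | None:
    """Calpha-Calpha Euclidean distance in A, or None if a residue is absent."""
    if not model.has_residue(chain_a, res_a) or not model.has_residue(
        chain_b, res_b
    ):
        return None
    return float(np.linalg.norm(model.ca(chain_a, res_a) - model.ca(chain_b, res_b)))


def resolve_assignment(
    model: StructureModel,
    pair: CrosslinkPair,
    chains: Mapping[str, Sequence[str]],
    mode: str = "min",
    limit: float = DEFAULT_LIMIT,
    offsets: Mapping[str, int] | None = None,
) -> DistanceRecord:
    """Assign chains to a residue pair and evaluate its distance.

    ``chains`` maps each accession to its candidate chain ids in the model.
    ``mode="min"`` evaluates every chain-assignment combination (intra- and
    inter-chain for a homomultimer) and keeps the minimal distance;
    ``mode="fixed"`` uses the pair's chain hints. ``offsets`` optionally maps
    chain id -> integer added to sequence positions to reach author numbering.
    Pairs whose residues cannot be located are returned unmapped.
    """
    if mode not in ("min", "fixed"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    offsets = offsets or {}

    def _resnum(chain: str, seq_pos: int) -> int:
        return seq_pos + int(offsets.get(chain, 0))

    candidates: list[tuple[str, str, float]] = []
    if mode == "fixed":
        ca, cb = pair.chain_hint_a, pair.chain_hint_b
        if ca and cb:
            d = ca_distance(
                model, ca, _resnum(ca, pair.residue_a),
                cb, _resnum(cb, pair.residue_b),
            )
            if d is not None:
                candidates.append((ca, cb, d))
    else:
        for ca in chains.get(pair.protein_a, ()):  # noqa: B007
            for cb in chains.get(pair.protein_b, ()):
                d = ca_distance(
                    model, ca, _resnum(ca, pair.residue_a),
                    cb, _resnum(cb, pair.residue_b),
                )
                if d is not None:
                    candidates.append((ca, cb, d))
    if not candidates:
        return DistanceRecord(
            pair=pair, chain_a=None, chain_b=None, distance=None,
            satisfied=None,
        )
    chain_a, chain_b, dist = min(candidates, key=lambda c: c[2])
    at_limit = math.isclose(dist, limit, rel_tol=0.0, abs_tol=_LIMIT_EPS)
    return DistanceRecord(
        pair=pair,
        chain_a=chain_a,
        chain_b=chain_b,
        distance=dist,
        satisfied=bool(dist <= limit + _LIMIT_EPS),
        at_limit=at_limit,
    )


def distance_summary(
    records: Sequence[DistanceRecord], limit: float = DEFAULT_LIMIT
) -> DistanceSummary:
    """Summary counts at a distance limit; unmapped pairs excluded from the
    denominator (only displayable crosslinks count)."""
    mapped = [r for r in records if r.mapped]
    satisfied = [r for r in mapped if r.distance <= limit + _LIMIT_EPS]
    at_limit = [
        r
        for r in mapped
        if math.isclose(r.distance, limit, rel_tol=0.0, abs_tol=_LIMIT_EPS)
    ]
    fraction = len(satisfied) / len(mapped) if mapped else None
    return DistanceSummary(
        n_total=len(records),
        n_mapped=len(mapped),
        n_satisfied=len(satisfied),
        n_at_limit=len(at_limit),
        fraction_satisfied=fraction,
        limit=limit,
    )


def records_frame(records: Sequence[DistanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_a": [r.pair.protein_a for r in records],
            "residue_a": [r.pair.residue_a for r in records],
            "protein_b": [r.pair.protein_b for r in records],
            "residue_b": [r.pair.residue_b for r in records],
            "chain_a": [r.chain_a or "" for r in records],
            "chain_b": [r.chain_b or "" for r in records],
            "distance": [
                np.nan if r.distance is None else r.distance for r in records
            ],
            "satisfied": [
                "" if r.satisfied is None else str(bool(r.satisfied))
                for r in records
            ],
            "at_limit": [r.at_limit for r in records],
        }
    )
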