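"""Synthetic quantification matrices and structure fixtures with known truth.

The generators emulate the study designs the pipeline analyses:

* an irradiation time course in which the crosslinked yield of each signal
  protein grows as a saturating exponential ``plateau * (1 - exp(-k*t))``
  (first-order photochemistry), on top of a crosslink-independent,
  glycoprotein-flagged background of constant abundance; multiplicative
  log-normal measurement noise; intensity-dependent (left-censoring)
  missingness,
* a two-pulse mixture design: a short damage pulse (weight 1) followed by a
  five-fold longer capture pulse (weight 5); the observed intensity is the
  duration-weighted mixture of the protein's state during each pulse, so a
  recruited protein with a 4-fold state change shows an observed fold of
  ``(1 + 5*4)/(1 + 5) = 3.5``,
* random Calpha "structures" with crosslink pairs and their true distances,
  serialized as parseable PDB text.

Every generator is deterministic given its config seed and returns the
ground-truth parameters per protein for recovery tests.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CrosslinkPair, QuantMatrix, SampleMeta

__all__ = [
    "TimecourseConfig",
    "TwoPulseConfig",
    "generate_timecourse",
    "generate_two_pulse",
    "generate_structure_fixture",
]

DEFAULT_TIME_GRID = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)


@dataclass(frozen=True)
class TimecourseConfig:
    """Irradiation time-course generator settings.

    Defaults are the study conditions the pipeline is validated under:
    a {0,1,2,4,8,16,32,64} s grid, 3 replicates, 20% CV noise, true rate
    constants log-uniform over 10^-2.5 .. 10^-1 s^-1 (curves captured
    mid-rise on this grid, where the log-time ET50 estimator is ordered in
    the true rate), abundance scales spanning 4 orders of magnitude, and
    logistic left-censoring of faint entries.
    """

    n_proteins: int = 1000
    n_background: int = 100
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    n_replicates: int = 3
    rate_log10_range: tuple[float, float] = (-2.5, -1.0)
    plateau_range: tuple[float, float] = (0.5, 1.0)
    noise_cv: float = 0.2
    missing_logistic: tuple[float, float] = (np.log(300.0), 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if 0.0 not in self.time_grid:
            raise ValueError("time grid must include the unirradiated t=0")
        if self.rate_log10_range[0] > self.rate_log10_range[1]:
            raise ValueError("rate_log10_range must be ordered")
        if self.plateau_range[0] > self.plateau_range[1]:
            raise ValueError("plateau_range must be ordered")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_proteins < 0 or self.n_background < 0 \
                or self.n_proteins + self.n_background < 1:
            raise ValueError("invalid protein counts")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class TwoPulseConfig:
    """Two-pulse (damage + capture) mixture design settings."""

    pulse_weights: tuple[float, float] = (1.0, 5.0)
    n_recruited: int = 50
    n_released: int = 50
    n_stable: int = 900
    effect_fold: float = 4.0
    n_replicates: int = 3
    noise_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pulse_weights[0] <= 0 or self.pulse_weights[1] < 0:
            raise ValueError("pulse weights must be positive (second >= 0)")
        if self.effect_fold < 1:
            raise ValueError("effect_fold must be >= 1")
        if min(self.n_recruited, self.n_released, self.n_stable) < 0:
            raise ValueError("protein counts must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 for testing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _lognormal_noise(
    rng: np.random.Generator, shape: tuple[int, ...], cv: float
) -> np.ndarray:
    """Multiplicative noise with unit mean and the requested CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log(1.0 + cv**2)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=shape)


def generate_timecourse(
    cfg: TimecourseConfig,
) -> tuple[QuantMatrix, pd.DataFrame]:
    """Generate a time-course matrix plus its ground truth.

    Signal protein p at time t has expected intensity
    ``scale_p * plateau_p * (1 - exp(-k_p * t))``; background (glycoprotein)
    proteins have constant expected intensity ``scale_p`` at every time.
    Entries are censored to missing with probability
    ``1/(1 + exp(steepness*(ln(I) - midpoint)))`` (faint entries drop out).
    """
    rng = np.random.default_rng(cfg.seed)
    n_sig, n_bg = cfg.n_proteins, cfg.n_background
    n_total = n_sig + n_bg
    ids = [f"SIG{i:05d}" for i in range(n_sig)] + [
        f"GLYC{i:05d}" for i in range(n_bg)
    ]
    log10_k = rng.uniform(*cfg.rate_log10_range, size=n_total)
    k = 10.0 ** log10_k
    plateau = rng.uniform(*cfg.plateau_range, size=n_total)
    scale = 10.0 ** rng.uniform(4.0, 8.0, size=n_total)
    is_background = np.zeros(n_total, dtype=bool)
    is_background[n_sig:] = True

    times = np.array(sorted(cfg.time_grid))
    samples = []
    columns = []
    for t in times:
        for rep in range(1, cfg.n_replicates + 1):
            source = "none" if t == 0 else "led"
            samples.append(
                SampleMeta(
                    sample_id=f"t{t:g}_r{rep}",
                    condition="timecourse",
                    irradiation_time=float(t),
                    irradiation_source=source,
                    replicate=rep,
                )
            )
            columns.append(t)

    expected = np.empty((n_total, len(samples)))
    for j, t in enumerate(columns):
        yield_t = plateau * (1.0 - np.exp(-k * t))
        expected[:, j] = np.where(is_background, scale, scale * yield_t)

    noise = _lognormal_noise(rng, expected.shape, cfg.noise_cv)
    values = expected * noise

    midpoint, steepness = cfg.missing_logistic
    with np.errstate(divide="ignore", over="ignore"):
        log_i = np.where(values > 0, np.log(values), -np.inf)
        p_missing = 1.0 / (1.0 + np.exp(steepness * (log_i - midpoint)))
    missing = rng.uniform(size=values.shape) < p_missing
    values = np.where(missing | (values <= 0), np.nan, values)

    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "true_k": k,
            "true_plateau": plateau,
            "abundance_scale": scale,
            "is_background": is_background,
            "true_group_fold": 1.0,
            "role": np.where(is_background, "background", "stable"),
        }
    )
    qm = QuantMatrix(
        protein_ids=ids,
        intensities=values,
        samples=samples,
        flags=pd.DataFrame(
            {
                "contaminant": False,
                "reverse": False,
                "glycoprotein": is_background,
            },
            index=ids,
        ),
        log=[f"generate_timecourse: seed={cfg.seed}"],
    )
    return qm, truth


def generate_two_pulse(
    cfg: TwoPulseConfig,
) -> tuple[QuantMatrix, pd.DataFrame]:
    """Generate a two-condition (immediate / delayed) two-pulse matrix.

    Observed intensity is ``(w1*state1 + w2*state2)/(w1 + w2)``; in the
    "delayed" condition recruited proteins have ``state2 = fold * state1``,
    released proteins ``state1 / fold``, stable ones are unchanged; in the
    "immediate" condition ``state2 = state1`` for all.
    """
    rng = np.random.default_rng(cfg.seed)
    roles = (
        ["recruited"] * cfg.n_recruited
        + ["released"] * cfg.n_released
        + ["stable"] * cfg.n_stable
    )
    n_total = len(roles)
    if n_total == 0:
        raise ValueError("config generates no proteins")
    ids = [f"P{i:05d}" for i in range(n_total)]
    state1 = 10.0 ** rng.uniform(4.0, 8.0, size=n_total)
    fold = np.ones(n_total)
    fold[: cfg.n_recruited] = cfg.effect_fold
    fold[cfg.n_recruited : cfg.n_recruited + cfg.n_released] = (
        1.0 / cfg.effect_fold
    )
    w1, w2 = cfg.pulse_weights
    w_sum = w1 + w2
    expected_immediate = state1
    expected_delayed = (w1 * state1 + w2 * fold * state1) / w_sum

    samples = []
    blocks = []
    for cond, expect in (
        ("immediate", expected_immediate),
        ("delayed", expected_delayed),
    ):
        for rep in range(1, cfg.n_replicates + 1):
            samples.append(
                SampleMeta(
                    sample_id=f"{cond}_r{rep}",
                    condition=cond,
                    irradiation_time=6.0,  # 1 s damage + 5 s capture
                    irradiation_source="led",
                    replicate=rep,
                )
            )
            blocks.append(expect)
    values = np.column_stack(blocks)
    values = values * _lognormal_noise(rng, values.shape, cfg.noise_cv)

    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "true_k": np.nan,
            "true_plateau": np.nan,
            "abundance_scale": state1,
            "is_background": False,
            "true_group_fold": (w1 + w2 * fold) / w_sum,
            "role": roles,
        }
    )
    qm = QuantMatrix(
        protein_ids=ids,
        intensities=values,
        samples=samples,
        log=[f"generate_two_pulse: seed={cfg.seed}"],
    )
    return qm, truth


_PDB_ATOM = (
    "ATOM  {serial:>5d}  CA  ALA {chain}{resnum:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
)


def generate_structure_fixture(
    n_residues: int = 20,
    n_chains: int = 1,
    n_pairs: int = 10,
    seed: int = 0,
    chain_offset: float = 25.0,
) -> tuple[str, list[CrosslinkPair], pd.DataFrame]:
    """Random Calpha trace, sampled crosslink pairs, and true distances.

    Chain A is a random walk with ~3.8 A steps; further chains duplicate
    chain A's coordinates translated by a fixed vector (a synthetic
    homomultimer), so inter-chain distances differ from intra-chain ones by a
    known offset pattern. Returns PDB text parseable by
    :func:`photoxl.io_formats.read_structure`, the pair list (chain hints on
    chain A), and a table of true intra-/inter-chain distances computed
    directly from the emitted coordinates.
    """
    if n_residues < 2:
        raise ValueError("need >= 2 residues")
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_residues - 1, 3))
    steps *= 3.8 / np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    coords = np.round(coords, 3)  # PDB format precision

    chain_ids = [chr(ord("A") + c) for c in range(n_chains)]
    translation = np.array([chain_offset, 0.0, 0.0])
    buf = io.StringIO()
    serial = 1
    chain_coords = {}
    for c, cid in enumerate(chain_ids):
        shifted = np.round(coords + c * translation, 3)
        chain_coords[cid] = shifted
        for r in range(n_residues):
            buf.write(
                _PDB_ATOM.format(
                    serial=serial, chain=cid, resnum=r + 1,
                    x=shifted[r, 0], y=shifted[r, 1], z=shifted[r, 2],
                )
            )
            serial += 1
        buf.write("TER\n")
    buf.write("END\n")

    pairs = []
    rows = []
    for _ in range(n_pairs):
        i, j = sorted(rng.choice(n_residues, size=2, replace=False) + 1)
        pairs.append(
            CrosslinkPair(
                protein_a="SYNPROT", residue_a=int(i),
                protein_b="SYNPROT", residue_b=int(j),
                chain_hint_a="A", chain_hint_b="A",
            )
        )
        row = {"residue_a": int(i), "residue_b": int(j)}
        for ca in chain_ids:
            for cb in chain_ids:
                row[f"dist_{ca}{cb}"] = float(
                    np.linalg.norm(
                        chain_coords[ca][i - 1] - chain_coords[cb][j - 1]
                    )
                )
        rows.append(row)
    return buf.getvalue(), pairs, pd.DataFrame(rows)
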