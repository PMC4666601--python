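"""Synthetic longitudinal DCS cohort generator.

Emulates a two-group longitudinal bone-graft study in mice: autograft
(n=7) and allograft (n=10) animals measured at baseline (week 0, before
surgery) and weekly through week 9, at six positions P1-P6 spaced 1.5 mm
along the grafted femur plus one contralateral control position P7, at
four source-detector separations (2.9/3.6/4.3/5.0 mm), with 30 repeated
2-s autocorrelation curves per site.

The generative model is multiplicative-lognormal around a deterministic
relative-blood-flow trajectory:

    BFI(m, w, p, rho) = B(m, p) * rBF_true(g, p, w, rho) * exp(eps_week),
    BFI_repeat = BFI(m, w, p, rho) * exp(eps_repeat),

with B(m, p) the per-mouse-and-position baseline (lognormal, median
1e-8 cm^2/s, geometric SD 1.3), eps_week ~ N(0, sigma_week^2) the weekly
physiological fluctuation and eps_repeat ~ N(0, sigma_repeat^2) the
repeat-to-repeat wobble. Each repeat curve is the noiseless Siegert
model plus additive Gaussian noise on g2. All random streams are derived
deterministically from (master seed, mouse, week, position, separation,
repeat), so regenerating a cohort is byte-identical and changing one
mouse's id perturbs only that mouse's data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .forward import FlowModel, LagGrid, OpticalProperties, g1_semi_infinite, g2_siegert
from .inversion import AutocorrCurve, CurveMeta, GROUPS, POSITIONS

__all__ = [
    "CohortDesign",
    "TrajectoryTable",
    "NoiseModel",
    "default_lag_grid",
    "default_trajectory_table",
    "true_rbf",
    "simulate_curve",
    "simulate_cohort",
    "CohortSimulation",
]

NOISE_PROFILES = ("constant", "inv-sqrt-lag")

# stream tags for deterministic per-record seed derivation
_STREAM_BASELINE = 0
_STREAM_WEEK = 1
_STREAM_REPEAT = 2


def default_lag_grid(max_lag_s: float = 1e-2) -> LagGrid:
    """Multi-tau correlator lag grid.

    16 linear channels at 1 us dwell, then successive groups of 8
    channels whose dwell doubles per group (group g has dwell 2^g us),
    extended until the maximum lag reaches ``max_lag_s``.
    """
    lags = [1e-6 * (i + 1) for i in range(16)]
    t = lags[-1]
    g = 0
    while lags[-1] < max_lag_s:
        g += 1
        dwell = (2.0**g) * 1e-6
        for _ in range(8):
            t += dwell
            lags.append(t)
    return LagGrid(np.asarray(lags))


@dataclass(frozen=True)
class CohortDesign:
    """Study design: group sizes, visit schedule and probe geometry."""

    n_autograft: int = 7
    n_allograft: int = 10
    weeks: tuple[int, ...] = tuple(range(10))
    graft_positions: tuple[str, ...] = ("P1", "P2", "P3", "P4", "P5", "P6")
    contralateral_position: str | None = "P7"
    position_spacing_mm: float = 1.5
    separations_mm: tuple[float, ...] = (2.9, 3.6, 4.3, 5.0)
    repeats: int = 30
    integration_s: float = 2.0
    master_seed: int = 1

    def __post_init__(self) -> None:
        if self.n_autograft < 1 or self.n_allograft < 1:
            raise ValueError("group sizes must be >= 1")
        if not self.weeks or self.weeks[0] != 0:
            raise ValueError("weeks must start at 0 (pre-surgery baseline)")
        if any(p not in POSITIONS for p in self.graft_positions):
            raise ValueError(f"graft positions must be among {POSITIONS}")
        seps = self.separations_mm
        if any(s <= 0 for s in seps) or list(seps) != sorted(seps):
            raise ValueError("separations must be positive and sorted")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    @property
    def mice(self) -> list[tuple[str, str]]:
        """(mouse id, group) pairs, autograft first."""
        out = [(f"auto{i+1:02d}", "autograft") for i in range(self.n_autograft)]
        out += [(f"allo{i+1:02d}", "allograft") for i in range(self.n_allograft)]
        return out

    @property
    def positions(self) -> tuple[str, ...]:
        if self.contralateral_position is None:
            return self.graft_positions
        return self.graft_positions + (self.contralateral_position,)


# Default weekly rBF trajectories at the 5.0 mm reference separation.
# Both groups surge after surgery and relax back to baseline; the
# autograft group does so uniformly along the femur within ~2 weeks,
# while the allograft group peaks later and stays elevated longer the
# more distal the position (proximal ~2, central ~4, distal ~6 weeks
# above the 1.25 elevation threshold). The allograft contralateral leg
# shows a systemic echo of the surge; the autograft contralateral leg
# stays flat.
_AUTO = (1.00, 1.95, 1.85, 1.15, 1.08, 1.05, 1.02, 1.00, 1.00, 1.00)
_ALLO_P2 = (1.00, 1.55, 1.60, 1.12, 1.08, 1.05, 1.02, 1.00, 1.00, 1.00)
_ALLO_P4 = (1.00, 1.65, 1.99, 1.80, 1.45, 1.18, 1.10, 1.05, 1.02, 1.00)
_ALLO_P6 = (1.00, 1.50, 1.80, 1.95, 1.75, 1.55, 1.42, 1.12, 1.05, 1.00)
_ALLO_P7 = (1.00, 1.61, 1.47, 1.20, 1.12, 1.08, 1.05, 1.02, 1.00, 1.00)


def _blend(u: tuple[float, ...], v: tuple[float, ...]) -> tuple[float, ...]:
    return tuple((a + b) / 2.0 for a, b in zip(u, v))


@dataclass(frozen=True)
class TrajectoryTable:
    """True weekly rBF multipliers at the reference separation, per (group, position).

    Values at other separations follow the linear depth-scaling rule
    v(rho) = 1 + s(rho) * (v(ref) - 1): identity (s = 1) for the
    autograft group, and for the allograft group s interpolates linearly
    from ``allograft_scale_at_min`` at the shortest separation to 1 at
    the reference separation (shallow measurements see an attenuated
    version of the deep blood-flow change).
    """

    values: Mapping[tuple[str, str], tuple[float, ...]]
    ref_separation_mm: float = 5.0
    min_separation_mm: float = 2.9
    allograft_scale_at_min: float = 0.465

    def __post_init__(self) -> None:
        for (group, pos), traj in self.values.items():
            if group not in GROUPS or pos not in POSITIONS:
                raise ValueError(f"unknown (group, position) key ({group}, {pos})")
            if traj[0] != 1.0:
                raise ValueError(f"week-0 rBF must be exactly 1.0 for ({group}, {pos})")
            if any(not 0.5 <= v <= 3.0 for v in traj):
                raise ValueError(f"rBF trajectory out of [0.5, 3] for ({group}, {pos})")

    def separation_scale(self, group: str, separation_mm: float) -> float:
        if group == "autograft":
            return 1.0
        span = self.ref_separation_mm - self.min_separation_mm
        frac = (separation_mm - self.min_separation_mm) / span
        return self.allograft_scale_at_min + (1.0 - self.allograft_scale_at_min) * frac

    def true_rbf(self, group: str, position: str, week: int, separation_mm: float) -> float:
        """True rBF multiplier for a cell of the design (week 0 is exactly 1)."""
        key = (group, position)
        if key not in self.values:
            raise ValueError(f"no trajectory for (group={group}, position={position})")
        traj = self.values[key]
        if not 0 <= week < len(traj):
            raise ValueError(f"week {week} outside trajectory (0..{len(traj)-1})")
        if week == 0:
            return 1.0
        v_ref = traj[week]
        return 1.0 + self.separation_scale(group, separation_mm) * (v_ref - 1.0)


def default_trajectory_table() -> TrajectoryTable:
    """Default study trajectories (see module docstring)."""
    values: dict[tuple[str, str], tuple[float, ...]] = {}
    for p in ("P1", "P2", "P3", "P4", "P5", "P6"):
        values[("autograft", p)] = _AUTO
    values[("autograft", "P7")] = tuple([1.00] * 10)
    values[("allograft", "P1")] = _ALLO_P2
    values[("allograft", "P2")] = _ALLO_P2
    values[("allograft", "P3")] = _blend(_ALLO_P2, _ALLO_P4)
    values[("allograft", "P4")] = _ALLO_P4
    values[("allograft", "P5")] = _blend(_ALLO_P4, _ALLO_P6)
    values[("allograft", "P6")] = _ALLO_P6
    values[("allograft", "P7")] = _ALLO_P7
    return TrajectoryTable(values=values)


def true_rbf(
    group: str,
    position: str,
    week: int,
    separation_mm: float,
    trajectories: TrajectoryTable | None = None,
) -> float:
    """True rBF multiplier under the default (or given) trajectory table."""
    table = trajectories if trajectories is not None else default_trajectory_table()
    return table.true_rbf(group, position, week, separation_mm)


@dataclass(frozen=True)
class NoiseModel:
    """Variance components of the synthetic cohort.

    ``baseline_bfi_median``/``baseline_gsd``: lognormal spread of the
    per-mouse-and-position baseline BFI across the cohort;
    ``sigma_week``: per-visit physiological log-fluctuation;
    ``sigma_repeat``: repeat-to-repeat log-wobble within a visit;
    ``sigma0``/``profile``: additive Gaussian noise on g2, either flat
    across lags or decaying as sqrt(tau_1/tau_k) (default), mimicking
    the better-averaged long-lag channels of a multi-tau correlator.
    """

    baseline_bfi_median: float = 1e-8   # cm^2/s
    baseline_gsd: float = 1.3           # geometric SD across mouse x position
    sigma_week: float = 0.06            # log-scale, per mouse-week-site
    sigma_repeat: float = 0.03          # log-scale, per repeat
    sigma0: float = 0.003               # g2 noise amplitude
    profile: str = "inv-sqrt-lag"
    beta: float = 0.5

    def __post_init__(self) -> None:
        if self.baseline_bfi_median <= 0 or self.baseline_gsd < 1:
            raise ValueError("baseline median must be > 0 and geometric SD >= 1")
        if min(self.sigma_week, self.sigma_repeat, self.sigma0) < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.profile not in NOISE_PROFILES:
            raise ValueError(f"profile must be one of {NOISE_PROFILES}")
        if not 0 < self.beta <= 1:
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")

    def g2_sigma(self, lags_s: np.ndarray) -> np.ndarray:
        if self.profile == "constant":
            return np.full(lags_s.shape, self.sigma0)
        return self.sigma0 * np.minimum(1.0, np.sqrt(lags_s[0] / lags_s))


def _mouse_key(mouse: str) -> int:
    return zlib.crc32(mouse.encode())


def _rng(*components: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(components))


def _sep_key(separation_mm: float) -> int:
    return int(round(separation_mm * 10))


def simulate_curve(
    true_bfi: float,
    optics: OpticalProperties,
    rho: float,
    noise: NoiseModel,
    seed: int | np.random.Generator,
    lags: LagGrid | None = None,
    meta: CurveMeta | None = None,
) -> AutocorrCurve:
    """One synthetic g2 curve: Siegert model plus additive Gaussian noise.

    ``rho`` is the source-detector separation in cm. ``seed`` may be an
    integer or a ready ``numpy.random.Generator``; equal seeds give
    identical curves.
    """
    if lags is None:
        lags = default_lag_grid()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g1 = g1_semi_infinite(lags, optics, rho, FlowModel(bfi=true_bfi, beta=noise.beta))
    g2 = g2_siegert(g1, noise.beta)
    if noise.sigma0 > 0:
        g2 = g2 + noise.g2_sigma(lags.lags_s) * rng.standard_normal(lags.lags_s.size)
    if meta is None:
        meta = CurveMeta("sim", "autograft", 0, "P4", separation_mm=rho * 10.0)
    return AutocorrCurve(lags=lags, g2=g2, meta=meta)


@dataclass(frozen=True)
class CohortSimulation:
    """A fully specified synthetic cohort; curves are generated lazily."""

    design: CohortDesign
    trajectories: TrajectoryTable
    noise: NoiseModel
    optics: OpticalProperties
    lag_grid: LagGrid
    ground_truth: pd.DataFrame = field(repr=False)

    def iter_site_visits(self) -> Iterator[tuple[CurveMeta, list[AutocorrCurve]]]:
        """Yield (site metadata, list of repeat curves) per (mouse, week, position, separation)."""
        for row in self.ground_truth.itertuples(index=False):
            meta = CurveMeta(
                mouse=row.mouse, group=row.group, week=int(row.week),
                position=row.position, separation_mm=float(row.separation_mm),
            )
            yield meta, self._site_curves(meta, row.true_bfi)

    def iter_curves(self) -> Iterator[AutocorrCurve]:
        for _, curves in self.iter_site_visits():
            yield from curves

    def _site_curves(self, meta: CurveMeta, site_bfi: float) -> list[AutocorrCurve]:
        d, n = self.design, self.noise
        mkey = _mouse_key(meta.mouse)
        skey = _sep_key(meta.separation_mm)
        pkey = POSITIONS.index(meta.position)
        rho = meta.separation_mm / 10.0
        curves = []
        for rep in range(d.repeats):
            rng = _rng(d.master_seed, _STREAM_REPEAT, mkey, meta.week, pkey, skey, rep)
            rep_bfi = site_bfi * float(np.exp(n.sigma_repeat * rng.standard_normal()))
            curve = simulate_curve(
                rep_bfi, self.optics, rho, n, rng, self.lag_grid,
                meta=CurveMeta(meta.mouse, meta.group, meta.week, meta.position,
                               meta.separation_mm, repeat=rep),
            )
            curves.append(curve)
        return curves


def _ground_truth(
    design: CohortDesign, trajectories: TrajectoryTable, noise: NoiseModel
) -> pd.DataFrame:
    rows = []
    for mouse, group in design.mice:
        mkey = _mouse_key(mouse)
        for position in design.positions:
            pkey = POSITIONS.index(position)
            baseline = noise.baseline_bfi_median * float(
                np.exp(np.log(noise.baseline_gsd)
                       * _rng(design.master_seed, _STREAM_BASELINE, mkey, pkey).standard_normal())
            )
            for week in design.weeks:
                for sep in design.separations_mm:
                    rbf = trajectories.true_rbf(group, position, week, sep)
                    eps = _rng(design.master_seed, _STREAM_WEEK, mkey, week, pkey,
                               _sep_key(sep)).standard_normal()
                    bfi = baseline * rbf * float(np.exp(noise.sigma_week * eps))
                    rows.append((mouse, group, week, position, sep, rbf, bfi))
    return pd.DataFrame(
        rows,
        columns=["mouse", "group", "week", "position", "separation_mm",
                 "true_rbf", "true_bfi"],
    )


def simulate_cohort(
    design: CohortDesign = CohortDesign(),
    trajectories: TrajectoryTable | None = None,
    noise: NoiseModel | None = None,
    optics: OpticalProperties | None = None,
    lags: LagGrid | None = None,
) -> CohortSimulation:
    """Assemble a synthetic cohort simulation from the design blocks.

    Returns a :class:`CohortSimulation` whose ``ground_truth`` table holds
    the realized site-level BFI (baseline x trajectory x weekly
    fluctuation) and the noise-free true rBF per (mouse, week, position,
    separation); repeat curves are generated on demand.
    """
    trajectories = trajectories if trajectories is not None else default_trajectory_table()
    noise = noise if noise is not None else NoiseModel()
    optics = optics if optics is not None else OpticalProperties()
    lags = lags if lags is not None else default_lag_grid()
    truth = _ground_truth(design, trajectories, noise)
    return CohortSimulation(
        design=design, trajectories=trajectories, noise=noise,
        optics=optics, lag_grid=lags, ground_truth=truth,
    )
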