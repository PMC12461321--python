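"""Design-space enumeration and screening of candidate DES formulations.

The screen enumerates every unordered pair of distinct precursors as a
1:1 (equimolar) binary mixture, predicts its density and viscosity at
298 K and its melting temperature with three pretrained GPs, and retains
candidates passing a liquidity gate on the predicted melting point:
below 275 K for the low-density/low-viscosity search, below 300 K for
the high-density/high-viscosity search.  Retained candidates are ranked
by a rank-sum over the two objectives (viscosity ranked on a log scale),
with a Pareto-front mode available.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gp import TrainedGP
from .profiles import MixtureSpec, SigmaProfile, featurize_many

logger = logging.getLogger("desgp")

__all__ = [
    "GATE_LOW_K",
    "GATE_HIGH_K",
    "SCREEN_TEMPERATURE_K",
    "Candidate",
    "ScreeningResult",
    "enumerate_binary",
    "screen",
    "select_candidates",
    "pareto_front",
]

GATE_LOW_K = 275.0    # liquid well below room temperature
GATE_HIGH_K = 300.0   # liquid at room temperature
SCREEN_TEMPERATURE_K = 298.0


@dataclass(frozen=True)
class Candidate:
    """One 1:1 binary combination with its predicted properties."""

    pair: tuple[str, str]
    density: float                  # g/mL at the screen temperature
    viscosity: float                # cP at the screen temperature
    melting_temperature: float      # K
    density_sd: float
    viscosity_sd: float
    melting_temperature_sd: float

    def __post_init__(self) -> None:
        a, b = self.pair
        if a == b:
            raise ValueError(f"self-pair {self.pair}")
        if a > b:
            object.__setattr__(self, "pair", (b, a))


@dataclass
class ScreeningResult:
    """All screened candidates plus the conditions of the screen."""

    candidates: list[Candidate]
    temperature: float = SCREEN_TEMPERATURE_K
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame.from_records(
            [
                {
                    "comp1": c.pair[0],
                    "comp2": c.pair[1],
                    "density_g_mL": c.density,
                    "viscosity_cP": c.viscosity,
                    "melting_K": c.melting_temperature,
                    "density_sd": c.density_sd,
                    "viscosity_sd": c.viscosity_sd,
                    "melting_sd": c.melting_temperature_sd,
                }
                for c in self.candidates
            ]
        )
        if not df.empty:
            df["liquid_below_275K"] = df["melting_K"] < GATE_LOW_K
            df["liquid_below_300K"] = df["melting_K"] < GATE_HIGH_K
        return df


def enumerate_binary(precursor_ids: Sequence[str]) -> list[tuple[str, str]]:
    """All C(n, 2) unordered pairs of distinct precursors, in sorted order."""
    ids = list(precursor_ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate precursor ids: {dupes}")
    return list(itertools.combinations(sorted(ids), 2))


def screen(
    models: Mapping[str, TrainedGP],
    profiles: Mapping[str, SigmaProfile],
    pairs: Iterable[tuple[str, str]],
    temperature: float = SCREEN_TEMPERATURE_K,
) -> ScreeningResult:
    """Predict all three properties for every candidate pair, batched.

    Each pair is featurized as an equimolar binary mixture — with the
    screen temperature appended for the density and viscosity models and
    without it for melting temperature.  Pairs with a missing profile are
    skipped and logged, not fatal.  Batched prediction is exact: it goes
    through the same linear algebra as one-at-a-time calls.
    """
    for prop in ("density", "viscosity", "melting_temperature"):
        if prop not in models:
            raise KeyError(f"missing model for {prop!r}")
    kept: list[tuple[str, str]] = []
    skipped: list[tuple[str, str]] = []
    for pair in pairs:
        if pair[0] in profiles and pair[1] in profiles:
            kept.append(pair)
        else:
            skipped.append(pair)
            logger.warning("skipping %s: missing sigma profile", pair)
    if not kept:
        return ScreeningResult([], temperature=temperature, skipped=skipped)

    specs_t = [
        MixtureSpec(((a, 0.5), (b, 0.5)), temperature=temperature) for a, b in kept
    ]
    specs_nt = [MixtureSpec(((a, 0.5), (b, 0.5))) for a, b in kept]
    X_t = featurize_many(profiles, specs_t)
    X_nt = featurize_many(profiles, specs_nt)
    rho = models["density"].predict(X_t)
    eta = models["viscosity"].predict(X_t)
    tm = models["melting_temperature"].predict(X_nt)
    candidates = [
        Candidate(
            pair=pair,
            density=float(rho.mean[i]),
            viscosity=float(eta.mean[i]),
            melting_temperature=float(tm.mean[i]),
            density_sd=float(rho.sd[i]),
            viscosity_sd=float(eta.sd[i]),
            melting_temperature_sd=float(tm.sd[i]),
        )
        for i, pair in enumerate(kept)
    ]
    return ScreeningResult(candidates, temperature=temperature, skipped=skipped)


def select_candidates(
    result: ScreeningResult,
    mode: str,
    availability: Sequence[str] | None = None,
    top_k: int = 10,
    conservative: bool = False,
    pareto: bool = False,
) -> list[Candidate]:
    """Gate on predicted melting temperature and rank by the two objectives.

    ``mode='low'`` keeps candidates predicted liquid below 275 K and ranks
    ascending in (density, log viscosity); ``mode='high'`` keeps those
    liquid below 300 K and ranks descending.  ``availability`` restricts
    to pairs whose both members appear in the list.  Gating uses the
    predictive mean; ``conservative=True`` gates on mean + 1.96 sd instead.
    Ranking is the rank-sum of the two within-gate ranks (viscosity on a
    log scale, which leaves ranks unchanged but matches the objective's
    natural spread); ``pareto=True`` returns the Pareto front instead.
    Ties and ordering are deterministic (final tiebreak: pair ids).
    """
    if mode not in ("low", "high"):
        raise ValueError(f"mode must be 'low' or 'high', got {mode!r}")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    gate = GATE_LOW_K if mode == "low" else GATE_HIGH_K
    pool = result.candidates
    if availability is not None:
        avail = set(availability)
        pool = [c for c in pool if c.pair[0] in avail and c.pair[1] in avail]
    def gated_tm(c: Candidate) -> float:
        return c.melting_temperature + (
            1.96 * c.melting_temperature_sd if conservative else 0.0
        )
    pool = [c for c in pool if gated_tm(c) < gate]
    if not pool:
        logger.warning("no candidates pass the %.0f K gate", gate)
        return []
    sign = 1.0 if mode == "low" else -1.0
    dens = sign * np.array([c.density for c in pool])
    visc = sign * np.log10([c.viscosity for c in pool])
    if pareto:
        front = pareto_front(np.column_stack([dens, visc]))
        chosen = [pool[i] for i in front]
        chosen.sort(key=lambda c: (sign * c.density, sign * c.viscosity, c.pair))
        return chosen[:top_k]
    # rank-sum: scale-free bi-objective scalarization
    score = _ranks(dens) + _ranks(visc)
    order = sorted(range(len(pool)), key=lambda i: (score[i], pool[i].pair))
    return [pool[i] for i in order[:top_k]]


def _ranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (0-based), ties sharing their mean rank."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    ranks[order] = np.arange(len(values), dtype=float)
    # average ties
    for v in np.unique(values):
        mask = values == v
        if mask.sum() > 1:
            ranks[mask] = ranks[mask].mean()
    return ranks


def pareto_front(objectives: np.ndarray) -> list[int]:
    """Indices of non-dominated rows (minimization in every column)."""
    obj = np.asarray(objectives, dtype=float)
    n = obj.shape[0]
    front = []
    for i in range(n):
        dominated = np.any(
            np.all(obj <= obj[i], axis=1) & np.any(obj < obj[i], axis=1)
        )
        if not dominated:
            front.append(i)
    return front
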