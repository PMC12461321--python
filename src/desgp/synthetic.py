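"""Synthetic sigma-profile libraries and property datasets.

Real sigma profiles come from quantum-chemistry pipelines and the
property labels from experimental databases; neither is needed to
exercise this package.  The generator emulates their shape: each
compound's profile is a sum of Gaussian bumps on the 61-bin sigma grid
with a dominant bump near sigma = 0 and smaller wings (the qualitative
shape of real profiles), and labels come from a simple documented latent
function of the mixture descriptor plus Gaussian noise — additive in
log10 space for viscosity, whose real-world span covers many orders of
magnitude, and in label units otherwise.

The latent functions are deliberately plain (linear in low-order profile
moments, or a smooth RBF mixture) so a failure in a downstream model
test localizes to the model, not the fixture.  All randomness flows from
the single seed in :class:`SyntheticSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .datasets import PropertyDataset, save_dataset
from .profiles import (
    CANONICAL_GRID,
    FEATURE_LENGTH,
    MixtureSpec,
    SigmaProfile,
    featurize_mixture,
    write_profile,
)

__all__ = ["SyntheticSpec", "gen_profiles", "gen_dataset", "write_library"]

LATENT_FUNCTIONS = ("linear-in-moments", "smooth-RBF-mixture")

_PROP_STREAM = {"density": 1, "viscosity": 2, "melting_temperature": 3}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic fixture.

    Bump centers/widths are in e/A^2 on the sigma grid; ``area_range``
    is the total molecular surface area in A^2 (typical small molecules
    fall in the 60-250 A^2 range).  ``noise_sd`` is the label noise:
    log10 units for viscosity, label units for density (g/mL) and
    melting temperature (K).  ``viscosity_decades`` sets the approximate
    log10 span of noiseless viscosity labels.
    """

    n_compounds: int = 40
    bumps_range: tuple[int, int] = (2, 4)
    bump_center_range: tuple[float, float] = (-0.02, 0.02)
    bump_width_range: tuple[float, float] = (0.002, 0.006)
    area_range: tuple[float, float] = (60.0, 250.0)
    latent: str = "linear-in-moments"
    noise_sd: float = 0.05
    temperature_range: tuple[float, float] = (278.0, 368.0)
    viscosity_decades: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 2:
            raise ValueError("need at least 2 compounds")
        if self.latent not in LATENT_FUNCTIONS:
            raise ValueError(f"unknown latent function {self.latent!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.bump_center_range
        g = CANONICAL_GRID
        if lo < g.start or hi > g.start + g.step * (g.n_bins - 1):
            raise ValueError("bump centers must lie within the sigma grid")
        if self.bump_width_range[0] <= 0:
            raise ValueError("bump widths must be > 0")
        if self.temperature_range[0] <= 0:
            raise ValueError("temperatures must be > 0 K")


def gen_profiles(spec: SyntheticSpec) -> dict[str, SigmaProfile]:
    """Generate a compound library of Gaussian-bump sigma profiles.

    Each profile gets one dominant bump near sigma = 0 carrying most of
    the area plus smaller wing bumps, then is rescaled to a total area
    drawn from ``spec.area_range``.  Ids are C000, C001, ...
    """
    rng = np.random.default_rng([spec.seed, 11])
    centers = CANONICAL_GRID.centers()
    library: dict[str, SigmaProfile] = {}
    for i in range(spec.n_compounds):
        n_bumps = int(rng.integers(spec.bumps_range[0], spec.bumps_range[1] + 1))
        vals = np.zeros_like(centers)
        for b in range(n_bumps):
            if b == 0:  # dominant central bump
                mu = rng.normal(0.0, 0.004)
                mu = float(np.clip(mu, *spec.bump_center_range))
                weight = rng.uniform(0.5, 1.0)
            else:       # smaller wings
                mu = rng.uniform(*spec.bump_center_range)
                weight = rng.uniform(0.05, 0.35)
            width = rng.uniform(*spec.bump_width_range)
            vals += weight * np.exp(-((centers - mu) ** 2) / (2.0 * width**2))
        area = rng.uniform(*spec.area_range)
        vals *= area / vals.sum()
        cid = f"C{i:03d}"
        library[cid] = SigmaProfile(compound_id=cid, values=vals)
    return library


def _profile_moments(v183: np.ndarray) -> np.ndarray:
    """Low-order moments of the buffered-log descriptor, rescaled to O(1).

    Moments are taken on log(v + 1e-3) rather than on raw bin areas:
    property surfaces over sigma-profile space are smoothest on the log
    scale (which is also why log feature standardization performs best on
    real data), so the latent lives there too.  Centering/scale constants
    are fixed round numbers matching the default generator's moment
    statistics over random mixtures.
    """
    centers = np.tile(CANONICAL_GRID.centers(), 3)
    w = np.log(v183 + 1e-3)
    m0 = float(w.mean())
    m1 = float(w @ centers)
    m2 = float(w @ centers**2)
    return np.array([(m0 + 3.75) / 0.6, (m1 + 5.4) / 2.0, (m2 + 0.33) / 0.03])


def _sample_mixture(rng: np.random.Generator, ids: Sequence[str]) -> tuple:
    """Draw (component ids, mole fractions): 2 components (80%) or 3 (20%),
    Dirichlet(2) fractions rounded to 9 decimals summing exactly to one."""
    k = int(rng.choice([2, 3], p=[0.8, 0.2]))
    chosen = list(rng.choice(ids, size=k, replace=False))
    x = rng.dirichlet(np.full(k, 2.0))
    x = np.round(x, 9)
    x[-1] = 1.0 - x[:-1].sum()
    if np.any(x <= 0):  # rare degenerate draw; fall back to equimolar
        x = np.full(k, 1.0 / k)
        x[-1] = 1.0 - x[:-1].sum()
    return chosen, x


class _Latent:
    """Deterministic latent property function of the 183-entry descriptor.

    The raw functional (linear in profile moments, or an RBF mixture) is
    standardized against a fixed reference sample of 256 random mixtures
    from the same library, so the latent has mean 0 and sd 1 over the
    library's own mixture population regardless of library size or seed.
    """

    def __init__(self, spec: SyntheticSpec, property_name: str,
                 profiles: Mapping[str, SigmaProfile]):
        rng = np.random.default_rng([spec.seed, 101, _PROP_STREAM[property_name]])
        self.kind = spec.latent
        if self.kind == "linear-in-moments":
            c = rng.uniform(0.5, 1.0, size=3) * rng.choice([-1.0, 1.0], size=3)
            self.coef = c / np.sqrt(3.0)
        else:  # smooth-RBF-mixture: anchors at random pure-compound descriptors
            ids = rng.choice(sorted(profiles), size=min(6, len(profiles)),
                             replace=False)
            anchors = np.vstack(
                [featurize_mixture(profiles, MixtureSpec(((i, 1.0),)))
                 for i in ids]
            )
            self.anchors = anchors
            d = np.sqrt(((anchors[:, None] - anchors[None]) ** 2).sum(-1))
            self.h = float(np.median(d[np.triu_indices_from(d, k=1)])) or 1.0
            self.weights = rng.uniform(-2.0, 2.0, size=anchors.shape[0])
        self.loc, self.scale = 0.0, 1.0
        ref_rng = np.random.default_rng([spec.seed, 303])
        all_ids = sorted(profiles)
        ref = []
        for _ in range(256):
            chosen, x = _sample_mixture(ref_rng, all_ids)
            v = featurize_mixture(profiles, MixtureSpec(tuple(zip(chosen, x))))
            ref.append(self._raw(v[:FEATURE_LENGTH]))
        ref = np.array(ref)
        self.loc = float(ref.mean())
        self.scale = float(ref.std()) or 1.0

    def _raw(self, v183: np.ndarray) -> float:
        if self.kind == "linear-in-moments":
            return float(self.coef @ _profile_moments(v183))
        d2 = ((self.anchors - v183) ** 2).sum(axis=1)
        return float(self.weights @ np.exp(-d2 / (2.0 * self.h**2)))

    def __call__(self, v183: np.ndarray) -> float:
        return (self._raw(v183) - self.loc) / self.scale


def _label(
    property_name: str, z: float, temperature: float | None,
    noise: float, decades: float,
) -> float:
    if property_name == "density":
        # ~0.8-1.8 g/mL (real DES range) with a mild thermal-expansion term
        rho = 1.3 + 0.17 * z - 5e-4 * (temperature - 298.0) + noise
        return float(max(rho, 0.2))
    if property_name == "viscosity":
        # log-normal in z (linear on the log10 scale, like real viscosity
        # data); decreases with temperature, Arrhenius-like slope
        # centered near log10 = 1.8, the geometric center of real DES
        # viscosity data (~4e-3 .. 9e5 cP)
        log10_eta = (
            1.8 + decades / 6.0 * z - 0.012 * (temperature - 298.0) + noise
        )
        return float(10.0 ** log10_eta)
    # melting temperature, K: ~100-570 K like real DES data
    return float(np.clip(330.0 + 90.0 * z + noise, 60.0, 650.0))


def gen_dataset(
    spec: SyntheticSpec,
    property_name: str,
    n_rows: int,
    profiles: Mapping[str, SigmaProfile],
) -> PropertyDataset:
    """Sample labelled mixtures from the latent property function.

    Rows draw 2 components (80%) or 3 (20%) without replacement, Dirichlet
    mole fractions, and a uniform temperature where the property needs
    one.  The label is the latent function of the (temperature-free)
    183-entry descriptor plus the property's temperature term and noise.
    """
    if n_rows < 10:
        raise ValueError("n_rows must be >= 10")
    if property_name not in _PROP_STREAM:
        raise ValueError(f"unknown property {property_name!r}")
    uses_t = property_name in ("density", "viscosity")
    latent = _Latent(spec, property_name, profiles)
    rng = np.random.default_rng([spec.seed, 202, _PROP_STREAM[property_name]])
    ids = sorted(profiles)
    rows = []
    for _ in range(n_rows):
        chosen, x = _sample_mixture(rng, ids)
        temp = float(rng.uniform(*spec.temperature_range)) if uses_t else None
        mix = MixtureSpec(tuple(zip(chosen, x)), temperature=temp)
        v183 = featurize_mixture(profiles, MixtureSpec(tuple(zip(chosen, x))))
        z = latent(v183[:FEATURE_LENGTH])
        noise = float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else 0.0
        label = _label(property_name, z, temp, noise, spec.viscosity_decades)
        rows.append((mix, label))
    return PropertyDataset(property_name, rows)


def write_library(
    profiles: Mapping[str, SigmaProfile], directory,
    datasets: Mapping[str, PropertyDataset] | None = None,
) -> None:
    """Write profiles (and optionally datasets) in the on-disk formats."""
    directory = Path(directory)
    prof_dir = directory / "profiles"
    prof_dir.mkdir(parents=True, exist_ok=True)
    for cid in sorted(profiles):
        with open(prof_dir / f"{cid}.sigma", "w") as fh:
            write_profile(profiles[cid], fh)
    for name, ds in (datasets or {}).items():
        save_dataset(ds, directory / f"{name}.csv")
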