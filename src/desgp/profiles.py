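"""Sigma profiles and mixture featurization.

A sigma profile is the unnormalized histogram of a molecule's COSMO
screened surface charge density: for each charge-density bin sigma it
stores P(sigma)*A, the surface area (in square angstrom) carrying that
charge density.

Profiles are consumed as data (they come from quantum-chemistry
pipelines external to this package) on the standard COSMOtherm
discretization: 61 bins spanning -0.030 ... +0.030 e/A^2 in steps of
0.001 e/A^2, the only 0.001-step convention yielding a 61-entry vector.

A deep-eutectic-solvent mixture of up to three components with mole
fractions x_i is described by the concatenated, mole-fraction-weighted
profile

    SP = [SP_1 * x_1, SP_2 * x_2, SP_3 * x_3]

a 183-entry vector (3 slots of 61 bins; unused slots are zero blocks,
equivalent to x = 0).  For temperature-dependent properties the system
temperature in kelvin is appended as a 184th entry.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SigmaGrid",
    "SigmaProfile",
    "MixtureSpec",
    "CANONICAL_GRID",
    "N_BINS",
    "FEATURE_LENGTH",
    "MAX_COMPONENTS",
    "ProfileFormatError",
    "GridMismatchError",
    "read_profile",
    "write_profile",
    "featurize_mixture",
    "load_profile_library",
]

N_BINS = 61
MAX_COMPONENTS = 3
FEATURE_LENGTH = N_BINS * MAX_COMPONENTS  # 183


class ProfileFormatError(ValueError):
    """Raised when a sigma-profile file violates the two-column format."""


class GridMismatchError(ValueError):
    """Raised when a profile's sigma values do not lie on the canonical grid."""


@dataclass(frozen=True)
class SigmaGrid:
    """Uniform discretization of the screened charge density axis.

    The standard COSMOtherm convention: 61 bin centers from -0.030 to
    +0.030 e/A^2 in steps of 0.001 e/A^2.
    """

    start: float = -0.030
    step: float = 0.001
    n_bins: int = N_BINS

    def centers(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_bins)

    def __post_init__(self) -> None:
        if self.n_bins < 2 or self.step <= 0:
            raise ValueError("grid requires n_bins >= 2 and step > 0")


CANONICAL_GRID = SigmaGrid()


@dataclass(frozen=True)
class SigmaProfile:
    """One compound's 61-bin unnormalized polarity histogram.

    ``values[k]`` is P(sigma_k)*A in square angstrom; the sum over bins is
    the molecule's total COSMO surface area.
    """

    compound_id: str
    values: np.ndarray
    grid: SigmaGrid = CANONICAL_GRID

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (self.grid.n_bins,):
            raise ProfileFormatError(
                f"profile {self.compound_id!r}: expected {self.grid.n_bins} "
                f"values, got {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"profile {self.compound_id!r}: non-finite values")
        if np.any(vals < 0):
            raise ValueError(f"profile {self.compound_id!r}: negative area values")

    @property
    def total_area(self) -> float:
        """Total molecular surface area (A^2), the sum over all bins."""
        return float(self.values.sum())


@dataclass(frozen=True)
class MixtureSpec:
    """A mixture of 1-3 compounds with mole fractions summing to one.

    ``temperature`` (kelvin), when present, is appended to the feature
    vector; density and viscosity models use it, melting-temperature
    models do not.
    """

    components: tuple[tuple[str, float], ...]
    temperature: float | None = None

    def __post_init__(self) -> None:
        comps = tuple((str(c), float(x)) for c, x in self.components)
        object.__setattr__(self, "components", comps)
        if not 1 <= len(comps) <= MAX_COMPONENTS:
            raise ValueError(f"need 1..{MAX_COMPONENTS} components, got {len(comps)}")
        ids = [c for c, _ in comps]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate component ids: {ids}")
        xs = np.array([x for _, x in comps])
        if np.any(xs <= 0):
            raise ValueError("all mole fractions must be > 0")
        if abs(xs.sum() - 1.0) > 1e-9:
            raise ValueError(f"mole fractions sum to {xs.sum()!r}, expected 1")
        if self.temperature is not None:
            t = float(self.temperature)
            if not (t > 0 and np.isfinite(t)):
                raise ValueError(f"temperature must be positive, got {t}")
            object.__setattr__(self, "temperature", t)

    def canonical_components(self) -> tuple[tuple[str, float], ...]:
        """Components sorted by descending mole fraction, ties by id."""
        return tuple(sorted(self.components, key=lambda cx: (-cx[1], cx[0])))


def read_profile(source: IO[str] | str, compound_id: str) -> SigmaProfile:
    """Parse a two-column sigma-profile text stream.

    Lines starting with ``#`` are skipped.  Columns may be separated by
    whitespace or commas.  The sigma column must match the canonical grid
    to within 1e-9.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    sigmas: list[float] = []
    areas: list[float] = []
    for lineno, line in enumerate(source, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.replace(",", " ").split()
        if len(parts) != 2:
            raise ProfileFormatError(
                f"{compound_id!r} line {lineno}: expected 2 columns, got {len(parts)}"
            )
        try:
            sigmas.append(float(parts[0]))
            areas.append(float(parts[1]))
        except ValueError as exc:
            raise ProfileFormatError(
                f"{compound_id!r} line {lineno}: non-numeric entry"
            ) from exc
    if len(sigmas) != N_BINS:
        raise ProfileFormatError(
            f"{compound_id!r}: expected {N_BINS} data rows, got {len(sigmas)}"
        )
    expected = CANONICAL_GRID.centers()
    deltas = np.abs(np.array(sigmas) - expected)
    if deltas.max() > 1e-9:
        k = int(deltas.argmax())
        raise GridMismatchError(
            f"{compound_id!r}: sigma value {sigmas[k]} at row {k + 1} is off the "
            f"canonical grid (expected {expected[k]})"
        )
    return SigmaProfile(compound_id=compound_id, values=np.array(areas))


def write_profile(profile: SigmaProfile, sink: IO[str]) -> None:
    """Emit a profile as two-column text re-readable by :func:`read_profile`.

    Values are written with ``repr`` round-trip precision so that a
    write -> read cycle is bit-exact.
    """
    sink.write(f"# sigma profile: {profile.compound_id}\n")
    sink.write("# sigma (e/A^2)  P(sigma)*A (A^2)\n")
    for s, v in zip(profile.grid.centers(), profile.values):
        sink.write(f"{s:.6f} {float(v)!r}\n")


def featurize_mixture(
    profiles: Mapping[str, SigmaProfile], spec: MixtureSpec
) -> np.ndarray:
    """Build the concatenated mole-fraction-weighted mixture descriptor.

    Components are placed into the three 61-bin slots in canonical order
    (descending mole fraction, ties broken lexicographically by id), so
    the descriptor is invariant to the order components are listed in.
    Unused slots are zero.  Returns a length-183 vector, or 184 with
    ``spec.temperature`` appended as the final entry.
    """
    n = FEATURE_LENGTH + (1 if spec.temperature is not None else 0)
    out = np.zeros(n)
    for slot, (cid, x) in enumerate(spec.canonical_components()):
        try:
            prof = profiles[cid]
        except KeyError:
            raise KeyError(f"no sigma profile for compound {cid!r}") from None
        if prof.grid != CANONICAL_GRID:
            raise GridMismatchError(f"profile {cid!r} is not on the canonical grid")
        out[slot * N_BINS : (slot + 1) * N_BINS] = x * prof.values
    if spec.temperature is not None:
        out[-1] = spec.temperature
    return out


def featurize_many(
    profiles: Mapping[str, SigmaProfile], specs: Sequence[MixtureSpec]
) -> np.ndarray:
    """Stack :func:`featurize_mixture` over specs into an (n, d) matrix."""
    if not specs:
        raise ValueError("no mixtures to featurize")
    rows = [featurize_mixture(profiles, s) for s in specs]
    lengths = {r.shape[0] for r in rows}
    if len(lengths) > 1:
        raise ValueError("mixtures disagree on temperature presence")
    return np.vstack(rows)


def load_profile_library(directory) -> dict[str, SigmaProfile]:
    """Load every ``*.sigma``/``*.txt`` profile in a directory.

    The filename stem is the compound id.
    """
    from pathlib import Path

    directory = Path(directory)
    library: dict[str, SigmaProfile] = {}
    paths = sorted(
        p for p in directory.iterdir() if p.suffix in {".sigma", ".txt"}
    )
    if not paths:
        raise FileNotFoundError(f"no profile files (*.sigma, *.txt) in {directory}")
    for path in paths:
        with open(path) as fh:
            library[path.stem] = read_profile(fh, path.stem)
    return library
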