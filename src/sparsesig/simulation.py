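"""Synthetic tumor-cohort generator.

Cohorts are generated from the same model the solver assumes: each sample
draws a total mutation burden (log-uniform between 10^3 and 10^4.5 by
default, spanning typical whole-genome burdens), a subset of active
signatures (the designated background is always active; each other
signature is active with its presence fraction), Dirichlet-distributed
relative exposures over the active signatures scaled to the burden, and
per-cell Poisson counts around the expected spectrum ``alpha beta``.
Optional additive and additive+subtractive perturbations emulate
miscalled or dropped mutations beyond Poisson dispersion.

Six presets mirror the benchmark designs of the published evaluation:

* ``sim1`` — 116 samples, one dense background plus three sparse
  signatures (a prostate-like cohort);
* ``sim2`` — 100 samples, 4 signatures drawn at random from a catalog;
* ``sim3`` — as sim2 but restricted to dense signatures (>75% of
  categories contributing);
* ``sim4`` — as sim2 but restricted to sparse signatures (<50%
  contributing);
* ``sim5`` — as sim1 with additive and subtractive noise;
* ``sim6`` — 100 samples, 8 catalog signatures.

The catalog-based presets accept any signature table in the package TSV
format (e.g. a COSMIC catalog); without one they fall back to a
deterministic synthetic catalog built in :func:`synthetic_catalog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .background import load_preset
from .categories import CATEGORIES, CountMatrix
from .factorization import ExposureSet

PRESET_NAMES = ("sim1", "sim2", "sim3", "sim4", "sim5", "sim6")

#: probability above which a category "contributes" to a signature
#: (1% of the uniform level 1/96)
CONTRIBUTION_THRESHOLD = 1.0 / 960.0

DEFAULT_BURDEN_RANGE = (1e3, 10 ** 4.5)


@dataclass
class SimulationSpec:
    """Everything needed to draw one synthetic cohort."""

    n_samples: int
    signatures: np.ndarray            # (K_total, 96), rows sum to 1
    background_index: int | None = 0  # row acting as the always-on background
    presence_fraction: np.ndarray | float = 0.7
    burden_range: tuple[float, float] = DEFAULT_BURDEN_RANGE
    dirichlet_concentration: float = 1.0
    noise: str = "none"               # none | additive | additive_subtractive
    noise_rate: float = 0.0
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        self.signatures = np.atleast_2d(np.asarray(self.signatures, dtype=float))
        k = self.signatures.shape[0]
        if self.signatures.shape[1] != 96:
            raise ValueError("signatures must have 96 columns")
        pf = np.broadcast_to(
            np.asarray(self.presence_fraction, dtype=float), (k,)
        ).copy()
        if self.background_index is not None:
            pf[self.background_index] = 1.0
        if np.any(pf <= 0) or np.any(pf > 1):
            raise ValueError("presence fractions must lie in (0, 1]")
        self.presence_fraction = pf
        if self.noise not in ("none", "additive", "additive_subtractive"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise_rate < 0:
            raise ValueError("noise rate must be >= 0")
        lo, hi = self.burden_range
        if not 0 < lo <= hi:
            raise ValueError("burden_range must satisfy 0 < low <= high")


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    true_signatures: np.ndarray   # non-background rows
    true_exposures: ExposureSet
    spec: SimulationSpec

    @property
    def true_background(self) -> np.ndarray | None:
        if self.spec.background_index is None:
            return None
        return self.spec.signatures[self.spec.background_index]


def generate_exposures(spec: SimulationSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the full (n_samples x K_total) exposure matrix in counts.

    Per sample: activate each signature independently with its presence
    fraction (background always on; samples with no active signature are
    redrawn, bounded retries), draw Dirichlet weights over the active set,
    and scale them to a log-uniform total burden.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    k = spec.signatures.shape[0]
    lo, hi = spec.burden_range
    exposures = np.zeros((spec.n_samples, k))
    for i in range(spec.n_samples):
        for _ in range(100):
            active = rng.random(k) < spec.presence_fraction
            if active.any():
                break
        else:
            raise RuntimeError("could not activate any signature in 100 draws")
        burden = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
        weights = rng.dirichlet(
            np.full(int(active.sum()), spec.dirichlet_concentration)
        )
        exposures[i, active] = weights * burden
    return exposures


def simulate_counts(
    exposures: np.ndarray,
    signatures: np.ndarray,
    noise: str = "none",
    noise_rate: float = 0.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-cell Poisson counts around the expected spectrum ``alpha beta``.

    ``additive`` noise adds Poisson(noise_rate * mean cell value) counts to
    a random half of the cells; ``additive_subtractive`` additionally
    removes the same expected amount from another random half, floored at
    zero.
    """
    if noise_rate < 0:
        raise ValueError("noise rate must be >= 0")
    rng = np.random.default_rng(seed) if rng is None else rng
    expected = np.asarray(exposures, float) @ np.asarray(signatures, float)
    counts = rng.poisson(expected).astype(float)
    if noise != "none" and noise_rate > 0:
        mean_cell = expected.mean()
        bump = rng.poisson(noise_rate * mean_cell, size=counts.shape)
        counts += np.where(rng.random(counts.shape) < 0.5, bump, 0)
        if noise == "additive_subtractive":
            drop = rng.poisson(noise_rate * mean_cell, size=counts.shape)
            counts -= np.where(rng.random(counts.shape) < 0.5, drop, 0)
            np.maximum(counts, 0.0, out=counts)
    return counts


def simulate(spec: SimulationSpec) -> SimulatedDataset:
    """Draw a full cohort: exposures, counts, and retained ground truth."""
    rng = np.random.default_rng(spec.seed)
    exposures = generate_exposures(spec, rng)
    counts = simulate_counts(
        exposures, spec.signatures, noise=spec.noise,
        noise_rate=spec.noise_rate, rng=rng,
    )
    sample_ids = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    bg = spec.background_index
    non_bg = [k for k in range(spec.signatures.shape[0]) if k != bg]
    exp = ExposureSet(
        alpha0=exposures[:, bg] if bg is not None else None,
        alpha=exposures[:, non_bg],
    )
    return SimulatedDataset(
        counts=CountMatrix(counts, sample_ids),
        true_signatures=spec.signatures[non_bg],
        true_exposures=exp,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Signature catalogs


def contribution_fraction(signature: np.ndarray, threshold: float = CONTRIBUTION_THRESHOLD) -> float:
    """Fraction of the 96 categories contributing to a signature."""
    signature = np.asarray(signature, float)
    return float((signature > threshold).mean())


def _sparse_profile(rng: np.random.Generator, n_peaks: int) -> np.ndarray:
    v = np.zeros(96)
    peaks = rng.choice(96, size=n_peaks, replace=False)
    v[peaks] = rng.dirichlet(np.full(n_peaks, 0.8))
    return v


def _dense_profile(rng: np.random.Generator) -> np.ndarray:
    v = rng.dirichlet(np.full(96, 5.0))
    return v / v.sum()


def synthetic_catalog(n_signatures: int = 12, seed: int = 20231) -> pd.DataFrame:
    """Deterministic synthetic signature catalog (sparse/dense mix).

    A stand-in for an external catalog such as COSMIC: half the entries are
    sparse (10-25 contributing categories), half dense (all categories
    contributing). Returned as a signatures-format DataFrame (rows =
    signatures, columns = the 96 category labels).
    """
    rng = np.random.default_rng(seed)
    rows, index = [], []
    for s in range(n_signatures):
        if s % 2 == 0:
            rows.append(_sparse_profile(rng, int(rng.integers(10, 26))))
            index.append(f"SYN_sparse_{s + 1}")
        else:
            rows.append(_dense_profile(rng))
            index.append(f"SYN_dense_{s + 1}")
    return pd.DataFrame(rows, index=index, columns=list(CATEGORIES))


def load_catalog(path) -> pd.DataFrame:
    """Read a signature catalog TSV (rows = signatures, 96 label columns)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in CATEGORIES if c not in table.columns]
    if missing:
        raise ValueError(f"catalog is missing categories, e.g. {missing[:3]}")
    table = table[list(CATEGORIES)].astype(float)
    sums = table.sum(axis=1)
    return table.div(sums.where(sums > 0, 1.0), axis=0)


def _select_from_catalog(
    catalog: pd.DataFrame,
    n: int,
    rng: np.random.Generator,
    density: str = "any",
) -> np.ndarray:
    values = catalog.to_numpy(float)
    frac = np.array([contribution_fraction(v) for v in values])
    if density == "dense":
        pool = np.flatnonzero(frac > 0.75)
    elif density == "sparse":
        pool = np.flatnonzero(frac < 0.50)
    else:
        pool = np.arange(values.shape[0])
    if len(pool) < n:
        raise ValueError(
            f"catalog has only {len(pool)} {density} signatures; {n} needed"
        )
    chosen = rng.choice(pool, size=n, replace=False)
    return values[chosen]


def preset(name: str, catalog=None, seed: int = 0) -> SimulationSpec:
    """One of the six benchmark cohort designs (see module docstring).

    ``catalog`` may be a path to a signatures TSV or a DataFrame; presets
    sim2-sim6 draw their non-background signatures from it (falling back to
    :func:`synthetic_catalog`). sim1/sim5 use three fixed sparse profiles
    next to the germline background.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, PRESET_NAMES.index(name)]))
    background = load_preset("germline").probs
    if catalog is None:
        cat = synthetic_catalog()
    elif isinstance(catalog, pd.DataFrame):
        cat = catalog
    else:
        cat = load_catalog(catalog)

    if name in ("sim1", "sim5"):
        others = _select_from_catalog(cat, 3, rng, density="sparse")
        spec = SimulationSpec(
            n_samples=116,
            signatures=np.vstack([background, others]),
            background_index=0,
            presence_fraction=0.7,
            noise="additive_subtractive" if name == "sim5" else "none",
            noise_rate=0.1 if name == "sim5" else 0.0,
            seed=seed, name=name,
        )
        return spec

    n_sig = 8 if name == "sim6" else 4
    density = {"sim3": "dense", "sim4": "sparse"}.get(name, "any")
    others = _select_from_catalog(cat, n_sig - 1, rng, density=density)
    return SimulationSpec(
        n_samples=100,
        signatures=np.vstack([background, others]),
        background_index=0,
        presence_fraction=0.7,
        seed=seed, name=name,
    )


def replace_spec(spec: SimulationSpec, **changes) -> SimulationSpec:
    """Dataclass ``replace`` that re-runs validation."""
    return replace(spec, **changes)
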