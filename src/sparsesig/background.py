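"""Fixed background signatures.

A background signature is a dense 96-category probability spectrum held
constant during factorization, representing clock-like replication-error
mutagenesis (the SBS5-like / germline-like spectrum found across cancers
and normal tissue). Fixing it lets the solver attribute the ubiquitous flat
component to a single known signature instead of smearing it across the
discovered ones.

Two presets ship with the package, ``"germline"`` and ``"sbs5"``. The
packaged vectors are synthetic stand-ins (see ``data/*_synthetic.tsv``):
dense clock-like spectra constructed to carry the documented properties of
the published presets — CpG>TpG rates replaced by the corresponding CpA
rates, and a pairwise cosine similarity of 0.998 between the two.

Both presets apply the empirical CpG adjustment: because C>T at CpG sites
is dominated by deamination of methylated cytosine (a distinct process,
usually discovered as its own signature), the four NCG>NTG rates are
overwritten with the corresponding NCA>NTA rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .categories import CATEGORIES, CATEGORY_INDEX

PRESET_NAMES = ("germline", "sbs5")
DEFAULT_PRESET = "germline"

# NCG>NTG category overwritten by the matching NCA>NTA category
_CPG_RULE = {
    f"{n}[C>T]G": f"{n}[C>T]A" for n in ("A", "C", "G", "T")
}


@dataclass(frozen=True)
class BackgroundSignature:
    """A fixed 96-category probability vector (rows sum to 1)."""

    probs: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.shape != (96,):
            raise ValueError(f"background must have 96 entries, got {probs.shape}")
        if np.any(probs < 0):
            raise ValueError("background entries must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1 (use make_background)")

    def to_tsv(self, path) -> None:
        pd.Series(self.probs, index=list(CATEGORIES), name="probability").rename_axis(
            "category"
        ).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, name: str = "custom") -> "BackgroundSignature":
        table = pd.read_csv(path, sep="\t", index_col=0)
        vec = np.zeros(96)
        for label, value in table.iloc[:, 0].items():
            if label not in CATEGORY_INDEX:
                raise ValueError(f"unknown category label {label!r}")
            vec[CATEGORY_INDEX[label]] = float(value)
        return make_background(vec, name=name)


def cpg_adjust(v: np.ndarray) -> BackgroundSignature:
    """Replace NCG>NTG rates by the matching NCA>NTA rates, then renormalize.

    Idempotent: the overwritten entries no longer depend on their previous
    values, so applying the adjustment twice equals applying it once.
    """
    v = np.asarray(v, dtype=float).copy()
    if v.shape != (96,):
        raise ValueError(f"expected 96 entries, got {v.shape}")
    if np.any(v < 0):
        raise ValueError("entries must be non-negative")
    if not v.any():
        raise ValueError("all-zero spectrum cannot be adjusted")
    for target, source in _CPG_RULE.items():
        v[CATEGORY_INDEX[target]] = v[CATEGORY_INDEX[source]]
    return BackgroundSignature(v / v.sum(), name="custom")


def make_background(
    v, name: str = "custom", adjust: bool = False
) -> BackgroundSignature | None:
    """Build a custom background from a 96-vector, or ``None`` for "none".

    Passing ``"none"`` (or ``None``) selects the fitting path without a
    fixed background term, i.e. plain regularized NMF. With ``adjust=True``
    the CpG>TpG substitution rule is applied before normalization.
    """
    if v is None or (isinstance(v, str) and v.lower() == "none"):
        return None
    v = np.asarray(v, dtype=float)
    if v.shape != (96,):
        raise ValueError(f"background vector must have 96 entries, got {v.shape}")
    if np.any(v < 0):
        raise ValueError("background entries must be non-negative")
    if not v.any():
        raise ValueError("background vector is all zero")
    if adjust:
        adjusted = cpg_adjust(v)
        return BackgroundSignature(adjusted.probs, name=name)
    return BackgroundSignature(v / v.sum(), name=name)


def load_preset(name: str = DEFAULT_PRESET) -> BackgroundSignature:
    """Load one of the packaged preset backgrounds ("germline" or "sbs5").

    The packaged vectors are already CpG-adjusted and normalized.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    ref = resources.files("sparsesig.data").joinpath(f"{name}_synthetic.tsv")
    with resources.as_file(ref) as path:
        sig = BackgroundSignature.from_tsv(path, name=name)
    return sig
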