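"""Stabilisation of piercing residues: bulkiness maxima and B-factor minima.

A functionally relevant lasso is expected to have its piercing residue
mechanically stabilised.  Two per-residue profiles capture this:

* local *bulkiness* — windowed mean side-chain volume; the piercing of a
  stabilised lasso sits close to a local maximum (bulky residues cage the
  threaded segment);
* local *flexibility* — windowed mean crystallographic B-factor, or, for
  NMR ensembles, the mean square deviation (MSD) of CA positions across
  models after least-squares superposition; stabilised piercings sit near
  a local minimum.

The reported statistic is the sequential distance (in residues) from the
piercing residue to the nearest relevant extremum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Profile",
    "StabilityReport",
    "RESIDUE_VOLUMES",
    "bulkiness_profile",
    "bfactor_profile",
    "local_extrema",
    "piercing_extremum_distance",
    "UndefinedDistanceError",
]

#: amino-acid residue volumes (Angstrom^3), Zamyatnin-style consensus values
RESIDUE_VOLUMES = {
    "ALA": 88.6, "ARG": 173.4, "ASN": 114.1, "ASP": 111.1, "CYS": 108.5,
    "GLN": 143.8, "GLU": 138.4, "GLY": 60.1, "HIS": 153.2, "ILE": 166.7,
    "LEU": 166.7, "LYS": 168.6, "MET": 162.9, "PHE": 189.9, "PRO": 112.7,
    "SER": 89.0, "THR": 116.1, "TRP": 227.8, "TYR": 193.6, "VAL": 140.0,
}
_MEAN_VOLUME = float(np.mean(list(RESIDUE_VOLUMES.values())))

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


class UndefinedDistanceError(ValueError):
    pass


@dataclass
class Profile:
    values: np.ndarray  # one real per residue
    kind: str  # "bulkiness" | "bfactor" | "msd"
    window: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.window % 2 == 0:
            raise ValueError("smoothing window must be odd")


@dataclass
class StabilityReport:
    piercing_residue: int
    d_bulky: int | None
    d_bfac: int | None
    bfac_kind: str | None = None


def _windowed_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average, truncated (not padded) at the chain ends."""
    half = window // 2
    out = np.empty_like(values, dtype=float)
    n = len(values)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def bulkiness_profile(sequence, window: int = 5) -> Profile:
    """Local concentration of bulky residues along the sequence.

    ``sequence`` is a list of 3-letter codes, a 1-letter string, or a
    Chain; unknown residue codes take the mean volume.
    """
    if hasattr(sequence, "residues"):
        codes = [r.name for r in sequence.residues]
    elif isinstance(sequence, str):
        codes = [_ONE_TO_THREE.get(c.upper(), "UNK") for c in sequence]
    else:
        codes = list(sequence)
    if not codes:
        raise ValueError("empty sequence")
    vols = np.array([RESIDUE_VOLUMES.get(c.upper(), _MEAN_VOLUME) for c in codes])
    return Profile(_windowed_mean(vols, window), "bulkiness", window)


def _superpose(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares (Kabsch) fit of ``mobile`` onto ``ref``."""
    mc, rc = mobile.mean(axis=0), ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mobile - mc)
    return rot.apply(mobile - mc) + rc


def bfactor_profile(chain, window: int = 5) -> Profile:
    """Per-residue flexibility: windowed B-factor, or inter-model MSD.

    Crystal chains use the CA B-factors.  NMR chains (>= 2 models, or no
    B-factors) use the mean square deviation of CA positions across models
    about their mean, after superposing every model onto the first by a
    least-squares CA fit.
    """
    models = getattr(chain, "models", [])
    if len(models) >= 2:
        ref = np.asarray(models[0], dtype=float)
        fitted = [ref] + [_superpose(np.asarray(m, float), ref) for m in models[1:]]
        stack = np.stack(fitted)  # (n_models, n_res, 3)
        mean_pos = stack.mean(axis=0)
        msd = np.mean(np.sum((stack - mean_pos) ** 2, axis=2), axis=0)
        return Profile(_windowed_mean(msd, window), "msd", window)
    bfac = [r.bfactor for r in chain.residues]
    if any(b is None for b in bfac):
        raise ValueError(
            "chain has neither complete B-factors nor multiple models")
    return Profile(_windowed_mean(np.array(bfac, float), window), "bfactor", window)


def local_extrema(profile: Profile, mode: str) -> list[int]:
    """1-based indices of strict local extrema of a profile.

    A value strictly better than both neighbours is an extremum; a plateau
    of equal values that beats both flanks reports its midpoint.  Chain
    ends never qualify, so monotone profiles have none.
    """
    v = profile.values
    if len(v) < 3:
        raise ValueError("profile too short for extremum detection")
    better = (lambda a, b: a < b) if mode == "min" else (lambda a, b: a > b)
    out: list[int] = []
    i = 0
    n = len(v)
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if i > 0 and j < n - 1 and better(v[i], v[i - 1]) and better(v[i], v[j + 1]):
            out.append((i + j) // 2 + 1)
        i = j + 1
    return out


def piercing_extremum_distance(piercing_residue: int, extrema) -> int:
    """Sequential distance to the nearest extremum."""
    extrema = list(extrema)
    if not extrema:
        raise UndefinedDistanceError("no extrema: distance undefined")
    return min(abs(piercing_residue - e) for e in extrema)
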