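"""End-to-end lasso detection: structure -> per-loop types -> fingerprint.

The per-chain pipeline is: model gaps, detect bridges, extract covalent
loops, and for every loop span a minimal surface, intersect both terminal
tails with it, reduce the crossings to genuine piercings, classify, and
assemble the chain fingerprint.  A degenerate loop (e.g. collinear CAs)
is reported per-loop without aborting the remaining loops.  Given a fixed
configuration the result is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import structure_io as sio
from .classify import Fingerprint, LassoType, classify_loop, fingerprint
from .piercing import (Piercing, ReduceParams, UndefinedDistanceError,
                       bridge_piercing_distance, find_crossings,
                       reduce_crossings)
from .stability import (StabilityReport, bfactor_profile, bulkiness_profile,
                        local_extrema, piercing_extremum_distance)
from .surface import DegenerateSurfaceError, MinParams, minimize_surface, triangulate_loop

__all__ = ["Config", "LoopResult", "ChainResult", "detect_chain", "detect_file"]


@dataclass
class Config:
    """All pipeline thresholds; logged verbatim into every result record."""

    max_ss_dist: float = 2.5  # Angstrom, CYS SG-SG disulfide cutoff
    use_links: bool = True
    permissive: bool = False  # distance-based non-disulfide bridge inference
    min_tail_depth: int = 3  # residues of tail required beyond a piercing
    cancel_eps: float = 2.0  # Angstrom, wobble cancellation radius
    cancel_sep: int = 1  # residues, wobble cancellation separation
    max_iter: int = 200  # surface relaxation sweeps
    rel_tol: float = 1e-4  # surface relative-area convergence tolerance
    max_edge: float | None = None  # Angstrom, refinement threshold
    flip_signs: bool = False  # mirror the global sign convention
    window: int = 5  # residues, stability profile smoothing window
    max_loop_gap: int = 2  # residues, artifact threshold for gaps in loops
    stability: bool = False  # compute per-piercing stability distances

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class LoopResult:
    loop: sio.CovalentLoop
    lasso_type: LassoType | None
    piercings_n: list[Piercing] = field(default_factory=list)
    piercings_c: list[Piercing] = field(default_factory=list)
    distance: int | None = None  # bridge -> nearest piercing, residues
    validity: sio.ValidityReport | None = None
    surface_converged: bool = True
    error: str | None = None

    def to_record(self) -> dict:
        t = self.lasso_type
        return {
            "res_i": self.loop.res_i,
            "res_j": self.loop.res_j,
            "chemistry": self.loop.bridge.chemistry,
            "minor": t.minor if t else None,
            "major": t.major if t else None,
            "klass": t.klass if t else None,
            "n_signs": list(t.n_signs) if t else [],
            "c_signs": list(t.c_signs) if t else [],
            "distance": self.distance,
            "status": self.validity.status if self.validity else None,
            "reasons": self.validity.reasons if self.validity else [],
            "surface_converged": self.surface_converged,
            "error": self.error,
        }


@dataclass
class ChainResult:
    cid: str
    loops: list[LoopResult]
    fingerprint: Fingerprint
    stability: list[StabilityReport] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        return {
            "chain": self.cid,
            "loops": [lr.to_record() for lr in self.loops],
            "fingerprint": self.fingerprint.text,
            "stability": [dataclasses.asdict(s) for s in self.stability],
            "config": self.config,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_record(), **kwargs)


def _tail_polyline(chain, loop, tail: str):
    """Tail CA polyline in loop-outward order, attachment residue first."""
    if tail == "N":
        idx = list(range(loop.res_i, 0, -1))
        direction = -1
    else:
        idx = list(range(loop.res_j, len(chain) + 1))
        direction = 1
    pts = np.array([chain.residues[i - 1].ca for i in idx])
    return pts, idx, direction


def detect_chain(chain: sio.Chain, config: Config | None = None) -> ChainResult:
    """Run the full lasso-detection pipeline on one chain."""
    config = config or Config()
    if len(chain) >= 2:
        sio.model_gaps(chain)
    bridges = sio.detect_bridges(
        chain, max_ss_dist=config.max_ss_dist, use_links=config.use_links,
        permissive=config.permissive)
    loops = sio.extract_loops(chain, bridges)
    rparams = ReduceParams(config.min_tail_depth, config.cancel_eps, config.cancel_sep)
    mparams = MinParams(config.max_iter, config.rel_tol, config.max_edge)
    loop_results: list[LoopResult] = []
    for loop in loops:
        try:
            surf = minimize_surface(triangulate_loop(loop, chain), mparams)
        except DegenerateSurfaceError as exc:
            loop_results.append(LoopResult(loop, None, error=str(exc)))
            continue
        pier = {}
        for tail in ("N", "C"):
            pts, idx, direction = _tail_polyline(chain, loop, tail)
            crossings = find_crossings(
                surf, pts, tail, residue_indices=idx,
                chain_direction=direction, flip_signs=config.flip_signs)
            pier[tail] = reduce_crossings(crossings, len(idx) - 1, rparams)
        lasso_type = classify_loop(
            [p.crossing.sign for p in pier["N"]],
            [p.crossing.sign for p in pier["C"]])
        all_pier = pier["N"] + pier["C"]
        try:
            distance = bridge_piercing_distance(loop, all_pier)
        except UndefinedDistanceError:
            distance = None
        validity = sio.validate(
            chain, loop, max_loop_gap=config.max_loop_gap, piercings=all_pier)
        loop_results.append(LoopResult(
            loop, lasso_type, pier["N"], pier["C"], distance, validity,
            surface_converged=surf.converged))
    fp = fingerprint([lr.lasso_type for lr in loop_results if lr.lasso_type])
    result = ChainResult(chain.cid, loop_results, fp, config=config.to_dict())
    if config.stability:
        result.stability = _stability_reports(chain, loop_results, config)
    return result


def _stability_reports(chain, loop_results, config) -> list[StabilityReport]:
    bulky = bulkiness_profile(chain, window=config.window)
    maxima = local_extrema(bulky, "max")
    try:
        bfac = bfactor_profile(chain, window=config.window)
        minima = local_extrema(bfac, "min")
        bkind = bfac.kind
    except ValueError:
        minima, bkind = [], None
    reports = []
    for lr in loop_results:
        for p in lr.piercings_n + lr.piercings_c:
            res = p.crossing.segment[0]  # first residue of piercing segment
            d_bulky = (piercing_extremum_distance(res, maxima)
                       if maxima else None)
            d_bfac = (piercing_extremum_distance(res, minima)
                      if minima else None)
            reports.append(StabilityReport(res, d_bulky, d_bfac, bkind))
    return reports


def detect_file(path, format: str | None = None,
                config: Config | None = None) -> list[ChainResult]:
    """Read a structure file and run detection on every chain."""
    return [detect_chain(ch, config)
            for ch in sio.read_structure(path, format=format)]
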