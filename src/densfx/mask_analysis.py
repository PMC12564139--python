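"""Dice similarity and DSC-targeted mask perturbation.

The perturbation emulates plausible segmentation error: voxels are deleted
from successive erosion layers and added on successive dilation shells
(boundary-local, never scattered salt-and-pepper), with the delete/add
counts (k, m) solved in closed form from

    DSC(original, perturbed) = 2(|A| - k) / (2|A| - k + m).

Because the achieved DSC depends only on (k, m) — deletions are inside A and
additions outside A — the integer pair nearest the target is found by a
small local search, so the achieved value is within one voxel's resolution
of the target before any randomness enters.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DimensionError, EmptyROIError, FeasibilityError, ParameterError
from .io import Mask

__all__ = ["PerturbationPlan", "dice_coefficient", "perturb_to_dsc"]

_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def dice_coefficient(a: Mask, b: Mask) -> float:
    """DSC = 2|A n B| / (|A| + |B|); two empty masks compare as 1.0."""
    if a.shape != b.shape:
        raise DimensionError(f"mask shapes differ: {a.shape} vs {b.shape}")
    da = a.data.astype(bool)
    db = b.data.astype(bool)
    denom = int(da.sum()) + int(db.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((da & db).sum()) / denom


@dataclass(frozen=True)
class PerturbationPlan:
    """Target Dice, tolerance, edit mode and seed for one perturbation."""

    target_dsc: float
    tolerance: float = 0.005
    mode: str = "mixed"  # mixed | delete-only | add-only
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.target_dsc <= 1.0:
            raise ParameterError(f"target_dsc must be in (0, 1], got {self.target_dsc}")
        if not self.tolerance > 0:
            raise ParameterError("tolerance must be > 0")
        if self.mode not in ("mixed", "delete-only", "add-only"):
            raise ParameterError(f"unknown mode {self.mode!r}")


def _dsc_of(a: int, k: int, m: int) -> float:
    return 2.0 * (a - k) / (2.0 * a - k + m)


def _best_counts(a: int, plan: PerturbationPlan) -> tuple:
    """Integer (k, m) whose closed-form DSC is nearest the target."""
    d = plan.target_dsc
    if plan.mode == "mixed":
        k0 = int(round(a * (1.0 - d)))
        candidates = [
            (k, m)
            for k in range(max(0, k0 - 2), min(a, k0 + 2) + 1)
            for m in range(max(0, k0 - 2), k0 + 3)
        ]
    elif plan.mode == "delete-only":
        k0 = int(round(2.0 * a * (1.0 - d) / (2.0 - d)))
        candidates = [(k, 0) for k in range(max(0, k0 - 2), min(a, k0 + 2) + 1)]
    else:  # add-only
        m0 = int(round(2.0 * a * (1.0 - d) / d))
        candidates = [(0, m) for m in range(max(0, m0 - 2), m0 + 3)]
    k, m = min(candidates, key=lambda km: abs(_dsc_of(a, km[0], km[1]) - d))
    err = abs(_dsc_of(a, k, m) - d)
    if err > plan.tolerance:
        raise FeasibilityError(
            f"target DSC {d} not reachable within +/-{plan.tolerance} in mode "
            f"{plan.mode!r} on a {a}-voxel mask (best achievable "
            f"{_dsc_of(a, k, m):.4f})"
        )
    return k, m


def _take_layered(pool_layers, n: int, rng) -> np.ndarray:
    """Draw n voxel coordinates, exhausting each boundary layer in turn."""
    chosen = []
    for layer in pool_layers:
        if n <= 0:
            break
        coords = np.argwhere(layer)
        if coords.shape[0] == 0:
            continue
        take = min(n, coords.shape[0])
        sel = rng.permutation(coords.shape[0])[:take]
        chosen.append(coords[sel])
        n -= take
    if n > 0:
        raise FeasibilityError(f"boundary layers exhausted with {n} edits remaining")
    return np.concatenate(chosen) if chosen else np.empty((0, 3), dtype=np.intp)


def _erosion_layers(m: np.ndarray):
    cur = m.copy()
    while cur.any():
        inner = ndimage.binary_erosion(cur, _STRUCT)
        yield cur & ~inner
        if not inner.any():
            return
        cur = inner


def _dilation_shells(m: np.ndarray, n_shells: int = 2):
    cur = m.copy()
    for _ in range(n_shells):
        grown = ndimage.binary_dilation(cur, _STRUCT)
        yield grown & ~cur
        cur = grown


def perturb_to_dsc(mask: Mask, plan: PerturbationPlan) -> Mask:
    """Return a boundary-locally perturbed mask whose Dice against the
    original is within ``plan.tolerance`` of ``plan.target_dsc``.

    Additions stay within a 2-layer dilation of the original mask; a target
    requiring more added voxels than those shells hold raises
    :class:`FeasibilityError`.
    """
    if mask.is_empty():
        raise EmptyROIError("cannot perturb an empty mask")
    if plan.target_dsc == 1.0:
        return mask.with_data(mask.data.copy())
    a = mask.count()
    k, m = _best_counts(a, plan)
    rng = np.random.default_rng(plan.seed)
    mbool = mask.data.astype(bool)

    out = mbool.copy()
    if k > 0:
        dels = _take_layered(_erosion_layers(mbool), k, rng)
        out[dels[:, 0], dels[:, 1], dels[:, 2]] = False
    if m > 0:
        shells = list(_dilation_shells(mbool, n_shells=2))
        avail = int(sum(s.sum() for s in shells))
        if m > avail:
            raise FeasibilityError(
                f"target DSC {plan.target_dsc} needs {m} added voxels but only "
                f"{avail} lie within the 2-layer boundary shell"
            )
        adds = _take_layered(shells, m, rng)
        out[adds[:, 0], adds[:, 1], adds[:, 2]] = True
    return mask.with_data(out.astype(np.uint8))
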