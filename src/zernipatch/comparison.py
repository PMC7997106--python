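"""Similarity and complementarity scores between two patch descriptors.

Both scores are Manhattan (L1) distances between invariant vectors, so 0 means
identical (similarity) or perfectly matched (complementarity), and larger is
more different.  The shape channel is compared like-with-like in both modes.
The electrostatic channels differ:

* similarity averages the like pairings      (pos-pos + neg-neg) / 2
* complementarity averages the cross pairings (pos-neg + neg-pos) / 2

because a good binding partner apposes positive potential to negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .zernike import DescriptorVector, ZernikeDescriptor

__all__ = [
    "SimilarityScore",
    "manhattan_distance",
    "similarity",
    "complementarity",
    "electrostatic_pairings",
]


@dataclass(frozen=True)
class SimilarityScore:
    """Shape and electrostatic L1 distances under one comparison mode."""

    shape_distance: float
    electrostatic_distance: float
    mode: str  # "similarity" | "complementarity"
    pairings: dict | None = None  # the four raw electrostatic pairings

    def __post_init__(self) -> None:
        if self.mode not in ("similarity", "complementarity"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.shape_distance < 0 or self.electrostatic_distance < 0:
            raise ValueError("distances must be nonnegative")


def manhattan_distance(t: DescriptorVector, v: DescriptorVector) -> float:
    """L1 distance sum_i |T_i - V_i| between two invariant vectors."""
    if len(t) != len(v):
        raise ValueError(f"descriptor length mismatch: {len(t)} vs {len(v)}")
    return float(np.abs(t.values - v.values).sum())


def electrostatic_pairings(a: ZernikeDescriptor, b: ZernikeDescriptor) -> dict[str, float]:
    """All four raw electrostatic channel distances, for diagnostics."""
    return {
        "pos_pos": manhattan_distance(a.elec_pos, b.elec_pos),
        "neg_neg": manhattan_distance(a.elec_neg, b.elec_neg),
        "pos_neg": manhattan_distance(a.elec_pos, b.elec_neg),
        "neg_pos": manhattan_distance(a.elec_neg, b.elec_pos),
    }


def _check_orders(a: ZernikeDescriptor, b: ZernikeDescriptor) -> None:
    if a.order != b.order:
        raise ValueError(f"descriptor order mismatch: {a.order} vs {b.order}")


def similarity(a: ZernikeDescriptor, b: ZernikeDescriptor) -> SimilarityScore:
    """Like-with-like comparison: shape distance and the mean of the
    positive-positive and negative-negative electrostatic distances."""
    _check_orders(a, b)
    p = electrostatic_pairings(a, b)
    return SimilarityScore(
        shape_distance=manhattan_distance(a.shape, b.shape),
        electrostatic_distance=0.5 * (p["pos_pos"] + p["neg_neg"]),
        mode="similarity",
        pairings=p,
    )


def complementarity(a: ZernikeDescriptor, b: ZernikeDescriptor) -> SimilarityScore:
    """Cross comparison: shape distance (same as similarity) and the mean of
    the positive-negative and negative-positive electrostatic distances."""
    _check_orders(a, b)
    p = electrostatic_pairings(a, b)
    return SimilarityScore(
        shape_distance=manhattan_distance(a.shape, b.shape),
        electrostatic_distance=0.5 * (p["pos_neg"] + p["neg_pos"]),
        mode="complementarity",
        pairings=p,
    )
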