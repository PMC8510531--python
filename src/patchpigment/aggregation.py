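"""Replicate-set averaging and representative-replicate selection.

A strain/condition is photographed as many replicate patches (20 per
interaction condition, 12 for the isolated wild type in the original study
design).  Their 200-bin profiles are averaged per bin, and a single
"representative" replicate — the one closest to the across-replicate mean
profile in Euclidean distance — is picked for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiling import N_BREAKPOINTS, PigmentationProfile

__all__ = ["ReplicateSet", "AggregateProfile", "aggregate_profiles", "select_representative"]


@dataclass
class ReplicateSet:
    """Profiles of replicate patches of one strain/condition."""

    profiles: list[PigmentationProfile]
    condition_label: str = ""

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("replicate set must contain at least one profile")
        orientations = {p.orientation for p in self.profiles}
        if len(orientations) > 1:
            raise ValueError(f"mixed profile orientations in replicate set: {sorted(orientations)}")

    def matrix(self) -> np.ndarray:
        """Replicates × bins matrix of profile means."""
        return np.stack([p.mean for p in self.profiles])


@dataclass
class AggregateProfile:
    """Across-replicate per-bin mean and sample standard deviation."""

    mean: np.ndarray
    sd: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if len(self.mean) != N_BREAKPOINTS or len(self.sd) != N_BREAKPOINTS:
            raise ValueError(f"aggregate profiles must have {N_BREAKPOINTS} bins")


def aggregate_profiles(rs: ReplicateSet) -> AggregateProfile:
    """Per-bin mean and sample (n−1) SD across the replicates of a set."""
    m = rs.matrix()
    sd = m.std(axis=0, ddof=1) if m.shape[0] > 1 else np.zeros(m.shape[1])
    return AggregateProfile(mean=m.mean(axis=0), sd=sd, n=m.shape[0])


def select_representative(rs: ReplicateSet) -> int:
    """Index of the replicate closest (L2 over the 200 bin means) to the
    across-replicate mean profile; ties broken by lowest index."""
    m = rs.matrix()
    dists = np.linalg.norm(m - m.mean(axis=0), axis=1)
    return int(np.argmin(dists))
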