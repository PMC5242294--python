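"""Read-level co-methylation of neighboring CpGs.

Deep amplicon bisulfite sequencing reads out several neighboring CpGs on the
same DNA strand, so one can ask whether methylation at an anchor CpG (the
clock CpG of the amplicon) predicts methylation at its neighbors on the same
molecule. The conditional profile restricts to reads whose anchor carries a
given state (M or U) and reports, per neighbor CpG, the multiplicity-weighted
fraction of those reads that are methylated there. Companion statistics
compare clonally derived subpopulations against the bulk they came from: the
mean profile over many subclones converges back to the bulk profile, while
individual subclones scatter widely — the hallmark of stochastically
acquired, non-co-regulated methylation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import ReadMethylation

__all__ = [
    "ConditionalProfile",
    "conditional_profile",
    "subclone_mean_vs_bulk",
    "clone_heterogeneity",
]


@dataclass
class ConditionalProfile:
    """P(methylated at CpG j | anchor CpG in ``anchor_state``), per read.

    ``p[j]`` is the weighted fraction of anchor-state reads methylated at j
    (NaN where no informative read exists); ``n_anchor_reads`` the weighted
    number of reads with the requested anchor state. ``empty`` flags a
    profile with no anchor-state reads (no exception is raised).
    """

    amplicon: str
    anchor_index: int
    anchor_state: str
    p: np.ndarray
    n_anchor_reads: float

    @property
    def empty(self) -> bool:
        return self.n_anchor_reads == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "amplicon": self.amplicon,
                "anchor_state": self.anchor_state,
                "cpg_index": np.arange(len(self.p)),
                "p_methylated": self.p,
                "n_anchor_reads": self.n_anchor_reads,
            }
        )


def conditional_profile(
    reads: Sequence[ReadMethylation], anchor_index: int, anchor_state: str
) -> ConditionalProfile:
    """Methylation probability of every CpG conditional on the anchor state.

    Reads with an ambiguous (X) anchor are excluded entirely; reads with X at
    a non-anchor CpG are excluded only from that CpG's denominator. Weights
    are read multiplicities. By construction ``p[anchor_index]`` is 1.0 for
    anchor_state "M" and 0.0 for "U".
    """
    if anchor_state not in ("M", "U"):
        raise ValueError("anchor_state must be 'M' or 'U'")
    if not reads:
        raise ValueError("no reads given")
    n_cpgs = reads[0].n_cpgs
    if not 0 <= anchor_index < n_cpgs:
        raise ValueError(f"anchor_index {anchor_index} out of range for {n_cpgs} CpGs")
    amplicon = reads[0].amplicon

    states = np.array([list(r.states) for r in reads])
    mult = np.array([r.multiplicity for r in reads], dtype=float)
    keep = states[:, anchor_index] == anchor_state
    states, mult = states[keep], mult[keep]
    n_anchor = float(mult.sum())
    if n_anchor == 0:
        return ConditionalProfile(
            amplicon, anchor_index, anchor_state, np.full(n_cpgs, np.nan), 0.0
        )
    m = ((states == "M") * mult[:, None]).sum(axis=0)
    informative = ((states != "X") * mult[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(informative > 0, m / informative, np.nan)
    return ConditionalProfile(amplicon, anchor_index, anchor_state, p, n_anchor)


def subclone_mean_vs_bulk(
    clone_profiles: Sequence[np.ndarray | Sequence[float]],
    bulk_profile: np.ndarray | Sequence[float],
) -> pd.DataFrame:
    """Mean neighboring-CpG beta across subclones versus the parent bulk.

    Individual subclones carry essentially arbitrary epiallele patterns, but
    their unweighted mean per CpG converges back to the bulk level. Returns a
    DataFrame per CpG with ``clone_mean``, ``bulk_beta`` and ``difference``;
    ``df.attrs["max_abs_difference"]`` summarises the fit.
    """
    if len(clone_profiles) < 2:
        raise ValueError("need at least 2 clone profiles")
    mat = np.asarray([np.asarray(p, dtype=float) for p in clone_profiles])
    bulk = np.asarray(bulk_profile, dtype=float)
    if mat.shape[1] != bulk.shape[0]:
        raise ValueError(
            f"clone profiles have {mat.shape[1]} CpGs but bulk has {bulk.shape[0]}"
        )
    clone_mean = mat.mean(axis=0)
    diff = clone_mean - bulk
    out = pd.DataFrame(
        {
            "cpg_index": np.arange(len(bulk)),
            "clone_mean": clone_mean,
            "bulk_beta": bulk,
            "difference": diff,
        }
    )
    out.attrs["max_abs_difference"] = float(np.nanmax(np.abs(diff)))
    return out


def clone_heterogeneity(
    clone_profiles: Sequence[np.ndarray | Sequence[float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify between-clone scatter of neighboring-CpG methylation.

    Returns ``(per_cpg, per_clone)``: per CpG the SD of beta across clones
    (sample SD, n-1 denominator — clone counts are small), and per clone the
    max-minus-min beta across the amplicon's CpGs (within-molecule
    discordance of neighboring sites).
    """
    if len(clone_profiles) < 2:
        raise ValueError("need at least 2 clone profiles")
    mat = np.asarray([np.asarray(p, dtype=float) for p in clone_profiles])
    per_cpg = pd.DataFrame(
        {
            "cpg_index": np.arange(mat.shape[1]),
            "sd": mat.std(axis=0, ddof=1),
            "mean": mat.mean(axis=0),
        }
    )
    per_clone = pd.DataFrame(
        {
            "clone_index": np.arange(mat.shape[0]),
            "range": mat.max(axis=1) - mat.min(axis=1),
            "mean": mat.mean(axis=1),
        }
    )
    return per_cpg, per_clone
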