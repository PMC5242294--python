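"""Per-read methylation calling and per-CpG methylation levels.

After bisulfite conversion a methylated CpG cytosine reads ``C`` and an
unmethylated one reads ``T``; any other base at a CpG is scored ambiguous
(``X``) and excluded from methylation levels. Identical read sequences are
collapsed with a multiplicity count and, following the amplicon-sequencing
protocol this package models, only sequences observed at least
``min_multiplicity`` times (default 10) are retained; retained sequences
keep their full multiplicity so that per-CpG levels remain read
frequencies.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .amplicon_io import AmpliconSpec

logger = logging.getLogger(__name__)

DEFAULT_MIN_MULTIPLICITY = 10

__all__ = [
    "ReadMethylation",
    "call_read",
    "collapse_and_filter",
    "compute_beta",
    "conversion_qc",
    "patterns_to_frame",
    "DEFAULT_MIN_MULTIPLICITY",
]


@dataclass(frozen=True)
class ReadMethylation:
    """One (collapsed) read's CpG state vector.

    ``states`` is a string over ``M`` (methylated, read C), ``U``
    (unmethylated, read T) and ``X`` (ambiguous/other base or beyond the
    read end), one character per CpG of the amplicon; ``multiplicity`` is
    the number of identical read sequences it represents.
    """

    amplicon: str
    states: str
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if set(self.states) - set("MUX"):
            raise ValueError(f"invalid state characters in {self.states!r}")

    @property
    def n_cpgs(self) -> int:
        return len(self.states)


def call_read(read_seq: str, amplicon: AmpliconSpec) -> ReadMethylation:
    """Call M/U/X at each CpG offset of the amplicon for one read."""
    read_seq = read_seq.upper()
    states = []
    for o in amplicon.cpg_offsets:
        if o >= len(read_seq):
            states.append("X")
        elif read_seq[o] == "C":
            states.append("M")
        elif read_seq[o] == "T":
            states.append("U")
        else:
            states.append("X")
    return ReadMethylation(amplicon.name, "".join(states))


def collapse_and_filter(
    read_seqs: Iterable[str],
    amplicon: AmpliconSpec,
    min_multiplicity: int = DEFAULT_MIN_MULTIPLICITY,
) -> list[ReadMethylation]:
    """Collapse identical read sequences; drop rare ones.

    Sequences observed fewer than ``min_multiplicity`` times are removed (a
    PCR-family denoising step); survivors keep their full multiplicity so
    downstream levels stay frequencies over reads. Results are ordered by
    descending multiplicity, then sequence, for determinism.
    """
    counts = Counter(s.upper() for s in read_seqs)
    if not counts:
        logger.warning("collapse_and_filter: empty read set for %s", amplicon.name)
        return []
    kept = []
    for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        if n >= min_multiplicity:
            rm = call_read(seq, amplicon)
            kept.append(ReadMethylation(rm.amplicon, rm.states, n))
    return kept


def _state_matrix(reads: Sequence[ReadMethylation]) -> tuple[np.ndarray, np.ndarray]:
    states = np.array([list(r.states) for r in reads])
    mult = np.array([r.multiplicity for r in reads], dtype=float)
    return states, mult


def compute_beta(
    reads: Sequence[ReadMethylation], amplicon: AmpliconSpec | None = None
) -> pd.DataFrame:
    """Per-CpG methylation level: weighted M / (M + U), X excluded.

    Returns a DataFrame with one row per CpG: ``cpg_index``, ``offset`` (if
    an amplicon is given), weighted counts ``M``/``U``/``X``, ``beta`` and
    ``coverage`` (= M + U). ``beta`` is NaN where coverage is zero.
    """
    if not reads:
        n = amplicon.n_cpgs if amplicon is not None else 0
        return pd.DataFrame(
            {
                "cpg_index": range(n),
                "offset": list(amplicon.cpg_offsets) if amplicon is not None else [],
                "M": 0.0, "U": 0.0, "X": 0.0,
                "beta": np.nan, "coverage": 0.0,
            }
        )
    states, mult = _state_matrix(reads)
    m = ((states == "M") * mult[:, None]).sum(axis=0)
    u = ((states == "U") * mult[:, None]).sum(axis=0)
    x = ((states == "X") * mult[:, None]).sum(axis=0)
    coverage = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(coverage > 0, m / coverage, np.nan)
    if (coverage == 0).any():
        logger.warning("compute_beta: %d CpG(s) with zero coverage", int((coverage == 0).sum()))
    out = pd.DataFrame(
        {
            "cpg_index": np.arange(states.shape[1]),
            "M": m, "U": u, "X": x, "beta": beta, "coverage": coverage,
        }
    )
    if amplicon is not None:
        out.insert(1, "offset", list(amplicon.cpg_offsets))
    return out


def conversion_qc(read_seq: str, amplicon: AmpliconSpec) -> float:
    """Bisulfite-conversion QC: fraction of non-CpG reference cytosines read as C.

    Fully converted reads score 0.0; an entirely unconverted read scores
    1.0. Returns NaN (flagged undefined) for amplicons without non-CpG
    cytosines. Positions beyond the read end are ignored.
    """
    read_seq = read_seq.upper()
    sites = [o for o in amplicon.non_cpg_c_offsets if o < len(read_seq)]
    if not sites:
        logger.warning("conversion_qc: no non-CpG cytosines in %s", amplicon.name)
        return float("nan")
    retained = sum(read_seq[o] == "C" for o in sites)
    return retained / len(sites)


def patterns_to_frame(reads: Sequence[ReadMethylation]) -> pd.DataFrame:
    """Tabulate collapsed epiallele patterns (pattern string, multiplicity)."""
    return pd.DataFrame(
        {
            "amplicon": [r.amplicon for r in reads],
            "pattern": [r.states for r in reads],
            "multiplicity": [r.multiplicity for r in reads],
        }
    )
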