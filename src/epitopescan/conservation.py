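"""Epitope conservation across ortholog sets.

Quantifies how well conserved each epitope is within a set of related
sequences (e.g. a panel of pathogen strains), giving a ranking of
epitopes shared across strains or species.  Ortholog sequences are
supplied as FASTA; subjects are deduplicated and filtered by global
percent identity to the query protein, then each epitope is matched
ungapped against every window of every subject.  The conservation of an
epitope at identity level ``v`` is the fraction of subjects whose best
window identity reaches ``v``; sweeping ``v`` over a grid yields the
minimum-identity-versus-conservation curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_io import OrthologSet, OrthologSubject

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_LEVELS = tuple(float(v) for v in range(0, 101, 5))


@dataclass(frozen=True)
class ConservationParams:
    """Filtering and reporting parameters for a conservation analysis.

    ``min_ortholog_identity`` gates which subjects enter the analysis
    (inclusive, percent vs the query over a global alignment);
    ``identity_levels`` is the grid of epitope-identity thresholds at
    which conservation fractions are reported.
    """

    min_ortholog_identity: float = 0.0
    identity_levels: tuple[float, ...] = DEFAULT_IDENTITY_LEVELS
    dedupe: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_ortholog_identity <= 100.0:
            raise ValueError("min_ortholog_identity must lie in [0, 100]")
        levels = tuple(float(v) for v in self.identity_levels)
        if not levels:
            raise ValueError("identity_levels must be non-empty")
        if any(not 0.0 <= v <= 100.0 for v in levels):
            raise ValueError("identity levels must lie in [0, 100]")
        if list(levels) != sorted(levels):
            raise ValueError("identity_levels must be sorted ascending")
        object.__setattr__(self, "identity_levels", levels)


@dataclass
class ConservationResult:
    """Per-epitope conservation fractions over a filtered subject set."""

    epitope: str
    per_subject_best_identity: dict[str, float]
    conservation_at: dict[float, float]


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of two sequences over a global alignment.

    The alignment is global with BLOSUM62 scores and affine gap
    penalties (open -11, extend -1).  Identity is 100 x (identical
    aligned residue pairs) / (alignment length), with gap columns
    counted in the denominator.  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    alignment = _aligner().align(a.upper(), b.upper())[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


def filter_orthologs(oset: OrthologSet, params: ConservationParams) -> OrthologSet:
    """Deduplicate subjects and apply the minimum-identity gate.

    Exact-duplicate subject sequences are removed keeping the first
    occurrence; subjects below ``min_ortholog_identity`` percent
    identity to the query are dropped (the filter is inclusive: a
    subject exactly at the threshold is kept).  Order is preserved.
    """
    if not oset.subjects:
        raise ValueError("ortholog set has no subjects")
    kept: list[OrthologSubject] = []
    seen: set[str] = set()
    for sub in oset.subjects:
        if params.dedupe and sub.sequence in seen:
            continue
        if sub.percent_identity_to_query < params.min_ortholog_identity:
            continue
        kept.append(sub)
        seen.add(sub.sequence)
    if not kept:
        logger.warning(
            "identity filter at %.1f%% removed every subject", params.min_ortholog_identity
        )
    return OrthologSet(query=oset.query, subjects=kept)


def best_window_identity(epitope: str, subject: str) -> float:
    """Best ungapped match of an epitope anywhere in a subject sequence.

    Maximizes, over every window of the epitope's length in the
    subject, 100 x (identical residues) / (epitope length).  A subject
    shorter than the epitope scores 0 (with a warning).
    """
    n = len(epitope)
    if n < 1:
        raise ValueError("epitope must be non-empty")
    if len(subject) < n:
        logger.warning("subject shorter than epitope (%d < %d); identity 0", len(subject), n)
        return 0.0
    e = np.frombuffer(epitope.encode(), dtype="S1")
    s = np.frombuffer(subject.encode(), dtype="S1")
    windows = np.lib.stride_tricks.sliding_window_view(s, n)
    matches = (windows == e).sum(axis=1)
    return 100.0 * int(matches.max()) / n


def epitope_conservation(
    epitopes: Sequence[str],
    oset: OrthologSet,
    params: ConservationParams | None = None,
) -> list[ConservationResult]:
    """Conservation of each epitope across a filtered ortholog set.

    For each epitope the best ungapped window identity in every subject
    is computed; ``conservation_at(level)`` is the fraction of subjects
    whose best identity is at or above that level, for each level of
    the grid.  The (level, conservation) pairs form the
    minimum-identity-versus-conservation curve of the epitope.
    """
    params = params or ConservationParams()
    if not oset.subjects:
        raise ValueError("cannot compute conservation over an empty subject set")
    results = []
    for epitope in epitopes:
        best = {
            sub.subject_id: best_window_identity(epitope, sub.sequence)
            for sub in oset.subjects
        }
        vals = np.array(list(best.values()))
        conservation = {
            float(level): float((vals >= level).mean()) for level in params.identity_levels
        }
        results.append(
            ConservationResult(
                epitope=epitope,
                per_subject_best_identity=best,
                conservation_at=conservation,
            )
        )
    return results


def conservation_table(results: Iterable[ConservationResult]) -> pd.DataFrame:
    """Long-form (epitope, level, conservation_fraction) table."""
    rows = [
        {"epitope": r.epitope, "level": level, "conservation_fraction": frac}
        for r in results
        for level, frac in sorted(r.conservation_at.items())
    ]
    return pd.DataFrame(rows, columns=["epitope", "level", "conservation_fraction"])


def best_identity_table(results: Iterable[ConservationResult]) -> pd.DataFrame:
    """Long-form (epitope, subject_id, best_identity) table."""
    rows = [
        {"epitope": r.epitope, "subject_id": sid, "best_identity": ident}
        for r in results
        for sid, ident in r.per_subject_best_identity.items()
    ]
    return pd.DataFrame(rows, columns=["epitope", "subject_id", "best_identity"])
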