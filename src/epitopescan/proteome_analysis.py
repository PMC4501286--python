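"""Genome-wide analysis: thresholds, promiscuity, clusters, rankings.

Binder selection uses a *global percentage threshold on a per-allele
basis*: for each allele the scores of every peptide across the whole
proteome are pooled and the empirical quantile at each percentage level
is pre-computed.  A peptide is then a binder at level ``t`` when its
score reaches the top ``t`` percent of that allele's proteome-wide score
distribution — calibrated against the whole genome rather than within
one protein, which reflects the competitive binding of the full peptide
repertoire in an antigen-presenting cell.

Promiscuous binders are peptides that pass the threshold in at least
``k`` distinct alleles; clusters are dense runs of promiscuous binders
along a protein, a known indicator of T-cell epitope regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import Proteome, validate_results

PROMISCUOUS_COLUMNS = ("protein_id", "start", "peptide", "allele_count", "mean_score")
CLUSTER_COLUMNS = ("protein_id", "span_start", "span_end", "n_binders", "density")
SUMMARY_COLUMNS = (
    "protein_id",
    "length",
    "n_promiscuous",
    "binders_per_100aa",
    "n_clusters",
    "max_cluster_density",
)

#: Scores retained per allele before quantile computation.
DEFAULT_SAMPLE_CAP = 1_000_000


@dataclass
class AlleleThresholds:
    """Per-allele proteome-wide quantile cutoffs, indexed by percentage level.

    ``cutoff(allele, t)`` is the score at the ``1 - t/100`` empirical
    quantile of the allele's pooled scores: a peptide scoring at or
    above it sits in the top ``t`` percent proteome-wide.
    """

    method: str
    levels: tuple[float, ...]
    cutoffs: dict[tuple[str, float], float] = field(default_factory=dict)
    sample_cap: int = DEFAULT_SAMPLE_CAP

    @property
    def alleles(self) -> list[str]:
        return sorted({a for a, _ in self.cutoffs})

    def cutoff(self, allele: str, t: float) -> float:
        try:
            return self.cutoffs[(allele, float(t))]
        except KeyError:
            raise ValueError(
                f"no cutoff precomputed for allele '{allele}' at level {t}; "
                f"available levels: {sorted(self.levels)}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"method": self.method, "allele": a, "level": t, "cutoff": c}
            for (a, t), c in sorted(self.cutoffs.items())
        ]
        return pd.DataFrame(rows, columns=["method", "allele", "level", "cutoff"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sample_cap: int = DEFAULT_SAMPLE_CAP) -> "AlleleThresholds":
        methods = frame["method"].unique()
        if len(methods) != 1:
            raise ValueError("threshold table must contain exactly one method")
        cutoffs = {
            (str(r.allele), float(r.level)): float(r.cutoff) for r in frame.itertuples()
        }
        return cls(
            method=str(methods[0]),
            levels=tuple(sorted({t for _, t in cutoffs})),
            cutoffs=cutoffs,
            sample_cap=sample_cap,
        )


def compute_global_thresholds(
    results: pd.DataFrame,
    levels: Iterable[float],
    sample_cap: int = DEFAULT_SAMPLE_CAP,
    seed: int = 0,
) -> AlleleThresholds:
    """Pool scores per allele across the proteome and pre-compute quantile cutoffs.

    For each allele all scores across all proteins are pooled (a seeded
    uniform subsample of ``sample_cap`` is taken when the pool is
    larger).  ``cutoff(allele, t)`` is the empirical quantile at
    fraction ``q = 1 - t/100`` with linear interpolation between order
    statistics: with N sorted scores x_1..x_N and h = (N-1)q + 1,
    the cutoff is x_floor(h) + (h - floor(h)) (x_floor(h)+1 - x_floor(h)).
    """
    validate_results(results)
    if results.empty:
        raise ValueError("cannot compute thresholds from an empty result table")
    methods = results["method"].unique()
    if len(methods) != 1:
        raise ValueError(
            f"threshold calibration expects a single method, got: {', '.join(methods)}"
        )
    levels = tuple(sorted({float(t) for t in levels}))
    if not levels:
        raise ValueError("at least one percentage level is required")
    for t in levels:
        if not 0.0 < t <= 100.0:
            raise ValueError(f"percentage level {t} outside (0, 100]")
    if sample_cap < 1:
        raise ValueError("sample_cap must be >= 1")

    rng = np.random.default_rng(seed)
    cutoffs: dict[tuple[str, float], float] = {}
    for allele, group in results.groupby("allele", sort=True):
        scores = group["score"].to_numpy(dtype=float)
        if scores.size == 0:
            raise ValueError(f"allele '{allele}' has no scores")
        if scores.size > sample_cap:
            scores = scores[rng.choice(scores.size, size=sample_cap, replace=False)]
        qs = [1.0 - t / 100.0 for t in levels]
        cuts = np.quantile(scores, qs, method="linear")
        for t, c in zip(levels, cuts):
            cutoffs[(str(allele), t)] = float(c)
    return AlleleThresholds(
        method=str(methods[0]), levels=levels, cutoffs=cutoffs, sample_cap=sample_cap
    )


def select_binders(
    results: pd.DataFrame, thresholds: AlleleThresholds, t: float
) -> pd.DataFrame:
    """Keep the rows scoring at or above their own allele's cutoff at level ``t``.

    Selection is per-allele: a row is compared only against the cutoff
    of its allele.  Ties with the cutoff are kept (inclusive >=).
    """
    validate_results(results)
    if results.empty:
        return results.copy()
    missing = sorted(set(results["allele"].unique()) - set(thresholds.alleles))
    if missing:
        raise ValueError(f"alleles absent from thresholds: {', '.join(missing)}")
    cut = results["allele"].map(
        {a: thresholds.cutoff(a, t) for a in results["allele"].unique()}
    )
    return results.loc[results["score"] >= cut].copy()


def find_promiscuous(binders: pd.DataFrame, k: int = 1) -> pd.DataFrame:
    """Group binder rows by (protein, start, peptide) and keep peptides hit in >= k alleles.

    ``allele_count`` is the number of distinct alleles in which the
    peptide passed the threshold; ``mean_score`` is the mean score over
    those qualifying alleles.  Output is sorted by (protein_id, start).
    """
    validate_results(binders)
    if k < 1:
        raise ValueError("k must be >= 1")
    if binders.empty:
        return pd.DataFrame(columns=list(PROMISCUOUS_COLUMNS))
    grouped = (
        binders.groupby(["protein_id", "start", "peptide"], sort=False)
        .agg(allele_count=("allele", "nunique"), mean_score=("score", "mean"))
        .reset_index()
    )
    out = grouped.loc[grouped["allele_count"] >= k]
    return (
        out.sort_values(["protein_id", "start"], kind="mergesort")
        .reset_index(drop=True)[list(PROMISCUOUS_COLUMNS)]
    )


def find_clusters(
    promiscuous: pd.DataFrame, n: int = 9, g: int = 10, m: int = 3
) -> pd.DataFrame:
    """Chain promiscuous binders into positional clusters per protein.

    Binders occupy the residue interval ``[start, start + n - 1]``.
    Walking binders of one protein in start order, a binder joins the
    current cluster when the gap between its start and the running span
    end is at most ``g`` residues (single-linkage chaining, which for
    1-D intervals is exact connected-component clustering of the
    "gap <= g" interval graph).  Chains with fewer than ``m`` binders
    are discarded.  ``density = n_binders / span_length``.
    """
    if g < 0:
        raise ValueError("max gap g must be >= 0")
    if m < 1:
        raise ValueError("minimum cluster size m must be >= 1")
    if promiscuous.empty:
        return pd.DataFrame(columns=list(CLUSTER_COLUMNS))

    rows = []
    for protein_id, group in promiscuous.groupby("protein_id", sort=True):
        starts = np.sort(group["start"].to_numpy(dtype=int))
        span_start = int(starts[0])
        span_end = span_start + n - 1
        count = 1
        chains: list[tuple[int, int, int]] = []
        for s in starts[1:]:
            s = int(s)
            if s - span_end <= g:
                span_end = max(span_end, s + n - 1)
                count += 1
            else:
                chains.append((span_start, span_end, count))
                span_start, span_end, count = s, s + n - 1, 1
        chains.append((span_start, span_end, count))
        for span_start, span_end, count in chains:
            if count >= m:
                rows.append(
                    {
                        "protein_id": protein_id,
                        "span_start": span_start,
                        "span_end": span_end,
                        "n_binders": count,
                        "density": count / (span_end - span_start + 1),
                    }
                )
    return pd.DataFrame(rows, columns=list(CLUSTER_COLUMNS))


def summarize_proteome(
    proteome: Proteome | Mapping[str, int],
    promiscuous: pd.DataFrame,
    clusters: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Rank proteins by epitope-density metrics.

    Returns ``(summary, top_peptides, top_clusters)``:

    * summary — one row per protein (zeros when it has no binders) with
      length, promiscuous-binder count, binders per 100 residues,
      cluster count and highest cluster density;
    * top_peptides — promiscuous binders sorted by
      (allele_count desc, mean_score desc);
    * top_clusters — clusters sorted by density desc.

    ``proteome`` may be a :class:`Proteome` or a protein_id -> length
    mapping (as recorded in a prediction manifest).
    """
    lengths = proteome.lengths() if isinstance(proteome, Proteome) else dict(proteome)
    for frame, label in ((promiscuous, "promiscuous"), (clusters, "clusters")):
        if not frame.empty:
            unknown = sorted(set(frame["protein_id"]) - set(lengths))
            if unknown:
                raise ValueError(
                    f"{label} table references proteins not in the proteome: "
                    f"{', '.join(unknown)}"
                )

    n_prom = (
        promiscuous.groupby("protein_id").size() if not promiscuous.empty else pd.Series(dtype=int)
    )
    n_clust = (
        clusters.groupby("protein_id").size() if not clusters.empty else pd.Series(dtype=int)
    )
    max_dens = (
        clusters.groupby("protein_id")["density"].max()
        if not clusters.empty
        else pd.Series(dtype=float)
    )
    rows = []
    for pid, length in lengths.items():
        np_ = int(n_prom.get(pid, 0))
        nc = int(n_clust.get(pid, 0))
        rows.append(
            {
                "protein_id": pid,
                "length": length,
                "n_promiscuous": np_,
                "binders_per_100aa": 100.0 * np_ / length,
                "n_clusters": nc,
                "max_cluster_density": float(max_dens.get(pid, 0.0)),
            }
        )
    summary = pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
    top_peptides = (
        promiscuous.sort_values(
            ["allele_count", "mean_score"], ascending=[False, False], kind="mergesort"
        ).reset_index(drop=True)
        if not promiscuous.empty
        else promiscuous.copy()
    )
    top_clusters = (
        clusters.sort_values("density", ascending=False, kind="mergesort").reset_index(drop=True)
        if not clusters.empty
        else clusters.copy()
    )
    return summary, top_peptides, top_clusters
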