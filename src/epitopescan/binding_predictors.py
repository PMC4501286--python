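"""Epitope predictors behind one uniform contract.

Two concrete predictors are provided:

* ``tepitope`` — TEPITOPE-style MHC class II prediction: each allele is
  parameterized by a 9x20 position-specific scoring matrix and every
  9-mer in a protein gets the position-additive sum of its residue
  scores.  The published TEPITOPEPan matrices can be supplied at run
  time through :func:`load_matrix_file`; the repository itself ships
  only tiny fixture matrices.
* ``bcell-scale`` — linear B-cell epitope prediction by averaging a
  per-residue propensity scale (hydrophilicity, flexibility,
  antigenicity, ...) over a sliding window.

Both emit the standard result table (protein_id, method, allele, start,
peptide, score) with 1-based starts, so downstream thresholding and
genome-wide analysis are agnostic to which predictor produced a table.
Adapters for external tools implement the same :class:`PredictorSpec`
contract and plug into a :class:`PredictorRegistry`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import (
    AA_ALPHABET,
    RESULT_COLUMNS,
    FormatError,
    Proteome,
    validate_results,
)

logger = logging.getLogger(__name__)

#: Residue -> column index; 'X' maps to an extra zero-scoring slot.
_RESIDUE_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_RESIDUE_INDEX["X"] = 20

MHC2_METHOD = "tepitope"
BCELL_METHOD = "bcell-scale"


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_RESIDUE_INDEX[aa] for aa in sequence], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in sequence") from None


@dataclass(frozen=True)
class ScoringMatrix:
    """Per-allele n x 20 position-specific scoring matrix.

    ``values[p, r]`` is the score of residue ``AA_ALPHABET[r]`` at
    peptide position ``p`` (0-based internally; positions are 1..n in
    the file format).  An 'X' residue contributes 0 at any position.
    """

    allele: str
    values: np.ndarray
    n: int = 9

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.n, 20):
            raise ValueError(
                f"matrix for '{self.allele}' must be {self.n}x20, got {vals.shape}"
            )
        if not np.isfinite(vals).all():
            raise ValueError(f"matrix for '{self.allele}' contains non-finite cells")
        if self.n < 1:
            raise ValueError("peptide length n must be >= 1")
        # padded column 20 scores 0 for 'X'
        padded = np.zeros((self.n, 21))
        padded[:, :20] = vals
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "_padded", padded)

    def score(self, peptide: str) -> float:
        return score_peptide(self, peptide)


@dataclass(frozen=True)
class PropensityScale:
    """A 20-residue propensity scale averaged over a sliding window."""

    name: str
    values: Mapping[str, float]
    window: int = 7

    def __post_init__(self) -> None:
        missing = sorted(set(AA_ALPHABET) - set(self.values))
        if missing:
            raise ValueError(f"scale '{self.name}' missing residues: {', '.join(missing)}")
        vals = {aa: float(self.values[aa]) for aa in AA_ALPHABET}
        if not all(np.isfinite(v) for v in vals.values()):
            raise ValueError(f"scale '{self.name}' contains non-finite values")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        object.__setattr__(self, "values", vals)
        # lookup vector with 'X' -> 0
        vec = np.zeros(21)
        vec[:20] = [vals[aa] for aa in AA_ALPHABET]
        object.__setattr__(self, "_vector", vec)


# ---------------------------------------------------------------------------
# Core scanning and scoring
# ---------------------------------------------------------------------------

def scan_peptides(sequence: str, n: int) -> list[tuple[int, str]]:
    """Enumerate every n-mer of a sequence with its 1-based start.

    Returns exactly ``max(0, L - n + 1)`` entries in positional order; a
    sequence shorter than ``n`` yields an empty list.
    """
    if n < 1:
        raise ValueError("peptide length n must be >= 1")
    L = len(sequence)
    return [(i + 1, sequence[i : i + n]) for i in range(L - n + 1)]


def score_peptide(matrix: ScoringMatrix, peptide: str) -> float:
    """Position-additive matrix score of a single peptide.

    The score is the sum over positions p of ``values[p][peptide[p]]``,
    with 'X' contributing 0 wherever it occurs.
    """
    if len(peptide) != matrix.n:
        raise ValueError(
            f"peptide length {len(peptide)} does not match matrix length {matrix.n}"
        )
    idx = _encode(peptide)
    return float(matrix._padded[np.arange(matrix.n), idx].sum())


def _scan_scores(matrix: ScoringMatrix, sequence: str) -> np.ndarray:
    """Vectorized matrix scores of every n-mer window of a sequence."""
    n = matrix.n
    idx = _encode(sequence)
    if len(idx) < n:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(idx, n)
    return matrix._padded[np.arange(n)[None, :], windows].sum(axis=1)


def predict_mhc2(
    proteome: Proteome,
    matrices: Mapping[str, ScoringMatrix] | Iterable[ScoringMatrix],
    alleles: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Score every 9-mer of every protein against the requested allele matrices.

    Emits one row per (protein, allele, start); the total row count is
    ``|alleles| * sum(max(0, L - n + 1))`` over proteins.
    """
    by_allele = _as_matrix_map(matrices)
    if alleles is None:
        alleles = list(by_allele)
    else:
        unknown = [a for a in alleles if a not in by_allele]
        if unknown:
            raise ValueError(
                f"unknown alleles {', '.join(unknown)}; "
                f"available: {', '.join(sorted(by_allele))}"
            )
    frames = []
    for rec in proteome:
        for allele in alleles:
            matrix = by_allele[allele]
            scores = _scan_scores(matrix, rec.sequence)
            W = len(scores)
            if W == 0:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "protein_id": rec.protein_id,
                        "method": MHC2_METHOD,
                        "allele": allele,
                        "start": np.arange(1, W + 1),
                        "peptide": [rec.sequence[i : i + matrix.n] for i in range(W)],
                        "score": scores,
                    }
                )
            )
    if not frames:
        from .sequence_io import empty_results

        return empty_results()
    return pd.concat(frames, ignore_index=True)[list(RESULT_COLUMNS)]


def predict_bcell(proteome: Proteome, scale: PropensityScale) -> pd.DataFrame:
    """Sliding-window mean of a propensity scale over every protein.

    The score at each window is the arithmetic mean of the per-residue
    scale values ('X' contributes 0; the divisor stays the full window).
    The window substring is reported with its 1-based start; the scale
    name fills the allele column.  Proteins shorter than the window are
    skipped with a warning.
    """
    w = scale.window
    frames = []
    for rec in proteome:
        if len(rec) < w:
            logger.warning(
                "skipping protein '%s' (length %d < window %d)", rec.protein_id, len(rec), w
            )
            continue
        vals = scale._vector[_encode(rec.sequence)]
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        means = (csum[w:] - csum[:-w]) / w
        W = len(means)
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": rec.protein_id,
                    "method": BCELL_METHOD,
                    "allele": scale.name,
                    "start": np.arange(1, W + 1),
                    "peptide": [rec.sequence[i : i + w] for i in range(W)],
                    "score": means,
                }
            )
        )
    if not frames:
        from .sequence_io import empty_results

        return empty_results()
    return pd.concat(frames, ignore_index=True)[list(RESULT_COLUMNS)]


def _as_matrix_map(
    matrices: Mapping[str, ScoringMatrix] | Iterable[ScoringMatrix],
) -> dict[str, ScoringMatrix]:
    if isinstance(matrices, Mapping):
        return dict(matrices)
    out: dict[str, ScoringMatrix] = {}
    for m in matrices:
        if m.allele in out:
            raise ValueError(f"duplicate matrix for allele '{m.allele}'")
        out[m.allele] = m
    return out


# ---------------------------------------------------------------------------
# Parameter file I/O
# ---------------------------------------------------------------------------
#
# Matrix file format: one or more blocks of
#     #allele <name> n <length>
#     [#residues ACDEFGHIKLMNPQRSTVWY]
#     <length> whitespace-separated rows of 20 numeric cells
#
# Scale file format:
#     #name <label>
#     #window <odd int>
#     <residue>\t<value>   (20 lines)

def load_matrix_file(path: str | Path) -> list[ScoringMatrix]:
    path = Path(path)
    matrices: list[ScoringMatrix] = []
    allele: str | None = None
    n = 9
    rows: list[list[float]] = []
    header_line = 0

    def flush(line_no: int) -> None:
        nonlocal allele, rows
        if allele is None:
            return
        if len(rows) != n:
            raise FormatError(
                f"{path}:{line_no}: matrix '{allele}' has {len(rows)} rows, expected {n}"
            )
        matrices.append(ScoringMatrix(allele=allele, values=np.array(rows), n=n))
        allele, rows = None, []

    with path.open() as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#allele"):
                flush(line_no)
                parts = line.split()
                if len(parts) < 2:
                    raise FormatError(f"{path}:{line_no}: malformed #allele header")
                allele = parts[1]
                n = int(parts[3]) if len(parts) >= 4 and parts[2] == "n" else 9
                header_line = line_no
                continue
            if line.startswith("#residues"):
                declared = line.split(None, 1)[1].replace(" ", "") if " " in line else ""
                missing = sorted(set(AA_ALPHABET) - set(declared))
                if missing:
                    raise FormatError(
                        f"{path}:{line_no}: residue column(s) missing: {', '.join(missing)}"
                    )
                if declared != AA_ALPHABET:
                    raise FormatError(
                        f"{path}:{line_no}: residue columns must be in the fixed "
                        f"order {AA_ALPHABET}"
                    )
                continue
            if line.startswith("#"):
                continue
            if allele is None:
                raise FormatError(f"{path}:{line_no}: data row before any #allele header")
            cells = line.split()
            if len(cells) != 20:
                raise FormatError(
                    f"{path}:{line_no}: expected 20 residue columns, got {len(cells)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError:
                raise FormatError(f"{path}:{line_no}: non-numeric cell") from None
    flush(header_line + n + 1)
    if not matrices:
        raise FormatError(f"'{path}' contains no matrices")
    return matrices


def write_matrix_file(matrices: Iterable[ScoringMatrix], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for m in matrices:
            fh.write(f"#allele {m.allele} n {m.n}\n")
            fh.write(f"#residues {AA_ALPHABET}\n")
            for row in m.values:
                fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def load_scale_file(path: str | Path) -> PropensityScale:
    path = Path(path)
    name = path.stem
    window = 7
    values: dict[str, float] = {}
    with path.open() as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#name"):
                name = line.split(None, 1)[1].strip()
                continue
            if line.startswith("#window"):
                window = int(line.split(None, 1)[1])
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2 or len(parts[0]) != 1:
                raise FormatError(f"{path}:{line_no}: expected '<residue> <value>'")
            try:
                values[parts[0].upper()] = float(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{line_no}: non-numeric value") from None
    return PropensityScale(name=name, values=values, window=window)


def write_scale_file(scale: PropensityScale, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#name {scale.name}\n#window {scale.window}\n")
        for aa in AA_ALPHABET:
            fh.write(f"{aa}\t{scale.values[aa]:.17g}\n")


# ---------------------------------------------------------------------------
# Predictor contract and registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictorSpec:
    """The adapter contract every predictor implements.

    ``predict(proteome, alleles)`` must emit the standard result table
    whose method column equals ``name``.  External tool adapters (e.g. a
    netMHCIIpan wrapper) implement this same contract; downstream
    analysis never inspects which predictor produced a table.
    """

    name: str
    peptide_length: int
    alleles: tuple[str, ...]
    predict: Callable[[Proteome, Sequence[str] | None], pd.DataFrame]

    def run(self, proteome: Proteome, alleles: Sequence[str] | None = None) -> pd.DataFrame:
        result = validate_results(self.predict(proteome, alleles))
        if len(result) and not (result["method"] == self.name).all():
            raise ValueError(
                f"predictor '{self.name}' emitted rows with a foreign method label"
            )
        return result


class PredictorRegistry:
    """Name-indexed collection of :class:`PredictorSpec` objects."""

    def __init__(self) -> None:
        self._specs: dict[str, PredictorSpec] = {}

    def register(self, spec: PredictorSpec) -> "PredictorRegistry":
        if spec.name in self._specs:
            raise ValueError(f"predictor '{spec.name}' is already registered")
        self._specs[spec.name] = spec
        return self

    def get(self, name: str) -> PredictorSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise KeyError(
                f"no predictor '{name}'; registered: {', '.join(sorted(self._specs))}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def names(self) -> list[str]:
        return sorted(self._specs)


def make_mhc2_spec(
    matrices: Mapping[str, ScoringMatrix] | Iterable[ScoringMatrix],
) -> PredictorSpec:
    """Wrap a set of allele matrices as the built-in ``tepitope`` predictor."""
    by_allele = _as_matrix_map(matrices)
    lengths = {m.n for m in by_allele.values()}
    if len(lengths) != 1:
        raise ValueError("all matrices in one predictor must share a peptide length")
    return PredictorSpec(
        name=MHC2_METHOD,
        peptide_length=lengths.pop(),
        alleles=tuple(by_allele),
        predict=lambda proteome, alleles=None: predict_mhc2(proteome, by_allele, alleles),
    )


def make_bcell_spec(scale: PropensityScale) -> PredictorSpec:
    """Wrap a propensity scale as the built-in ``bcell-scale`` predictor."""
    return PredictorSpec(
        name=BCELL_METHOD,
        peptide_length=scale.window,
        alleles=(scale.name,),
        predict=lambda proteome, alleles=None: predict_bcell(proteome, scale),
    )
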