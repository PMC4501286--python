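"""Proteome input/output and synthetic-fixture generation.

Proteomes come in as annotated GenBank flat files (preferred: locus tags
are short, unique identifiers and CDS features carry product/gene
annotation) or as plain protein FASTA (assigned to the genome label
``"other"`` unless told otherwise).  Prediction results are persisted as
one CSV per (protein, method) so results can be retrieved per protein
without loading a whole run.

The module also provides the synthetic-data generators used throughout
the test suite and the ``simulate`` CLI command: random proteomes with
controllable composition, planting of high-scoring 9-mer motifs, and
ortholog sets produced by i.i.d. per-site substitution of a query
protein.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard residues in the fixed column order used everywhere.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Residues accepted in input sequences ('X' = unknown; scores 0).
VALID_RESIDUES = frozenset(AA_ALPHABET) | {"X"}

#: Column order of every prediction-result table.
RESULT_COLUMNS = ("protein_id", "method", "allele", "start", "peptide", "score")


class FormatError(ValueError):
    """Raised when an input file does not follow its declared format."""


def _check_sequence(seq: str, name: str) -> str:
    seq = seq.upper()
    if not seq:
        raise FormatError(f"record '{name}' has an empty sequence")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise FormatError(
            f"record '{name}' contains non-amino-acid characters: "
            f"{', '.join(sorted(bad))}"
        )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """A single identified protein with its genome membership."""

    protein_id: str
    genome_id: str
    sequence: str
    product: str = ""
    gene: str | None = None

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        object.__setattr__(self, "sequence", _check_sequence(self.sequence, self.protein_id))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """An ordered collection of proteins sharing one genome label."""

    genome_id: str
    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.genome_id != self.genome_id:
                raise ValueError(
                    f"record '{rec.protein_id}' has genome '{rec.genome_id}', "
                    f"expected '{self.genome_id}'"
                )
            if rec.protein_id in seen:
                raise ValueError(f"duplicate protein_id '{rec.protein_id}'")
            seen.add(rec.protein_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def get(self, protein_id: str) -> ProteinRecord:
        for rec in self.records:
            if rec.protein_id == protein_id:
                return rec
        raise KeyError(protein_id)

    @property
    def protein_ids(self) -> list[str]:
        return [rec.protein_id for rec in self.records]

    def lengths(self) -> dict[str, int]:
        return {rec.protein_id: len(rec) for rec in self.records}


@dataclass(frozen=True)
class OrthologSubject:
    subject_id: str
    sequence: str
    percent_identity_to_query: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity_to_query <= 100.0:
            raise ValueError("percent_identity_to_query must lie in [0, 100]")


@dataclass
class OrthologSet:
    """A query protein plus candidate ortholog sequences.

    Subjects may contain exact duplicates until
    :func:`epitopescan.conservation.filter_orthologs` is applied.
    """

    query: ProteinRecord
    subjects: list[OrthologSubject] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.subjects)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_genbank(path: str | Path, genome_id: str | None = None) -> Proteome:
    """Read a GenBank flat file into a :class:`Proteome`.

    One :class:`ProteinRecord` is produced per CDS feature.  The protein
    id is the ``locus_tag`` qualifier, falling back to ``gene`` and then
    to a generated index-based id.  The amino-acid sequence is taken from
    the ``translation`` qualifier when present, otherwise the CDS span is
    translated with the standard codon table; a CDS with neither is
    skipped with a warning.

    Parameters
    ----------
    path:
        GenBank flat file (may contain several records; all CDS features
        are pooled into one proteome).
    genome_id:
        Override for the genome label; defaults to the first record's
        LOCUS name.
    """
    path = Path(path)
    try:
        gb_records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise FormatError(f"could not parse '{path}' as GenBank: {exc}") from exc
    if not gb_records:
        raise FormatError(f"'{path}' contains no GenBank records")

    if genome_id is None:
        genome_id = gb_records[0].name or gb_records[0].id

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    index = 0
    for gb in gb_records:
        for feat in gb.features:
            if feat.type != "CDS":
                continue
            index += 1
            quals = feat.qualifiers
            locus = quals.get("locus_tag", [None])[0]
            gene = quals.get("gene", [None])[0]
            product = quals.get("product", [""])[0]
            protein_id = locus or gene or f"CDS{index:04d}"
            if protein_id in seen:
                raise FormatError(f"duplicate locus tag '{protein_id}' in '{path}'")

            translation = quals.get("translation", [None])[0]
            if translation is None:
                try:
                    nt = feat.extract(gb.seq)
                    if len(nt) == 0 or len(nt) % 3 != 0:
                        raise ValueError(f"coding span length {len(nt)} not a codon multiple")
                    translation = str(nt.translate(table="Standard")).rstrip("*")
                    if "*" in translation:
                        raise ValueError("internal stop codon")
                except Exception as exc:
                    logger.warning(
                        "skipping CDS '%s': no translation qualifier and no valid "
                        "coding span (%s)", protein_id, exc,
                    )
                    continue
            records.append(
                ProteinRecord(
                    protein_id=protein_id,
                    genome_id=genome_id,
                    sequence=translation,
                    product=product,
                    gene=gene,
                )
            )
            seen.add(protein_id)
    return Proteome(genome_id=genome_id, records=records)


def read_fasta(path: str | Path, genome_id: str = "other") -> Proteome:
    """Read a protein FASTA file into a :class:`Proteome`.

    The protein id is the first whitespace-delimited token of each
    description line; the rest of the line becomes the product
    description.  Sequences are upper-cased; characters outside the
    20-letter alphabet plus 'X' are rejected.
    """
    path = Path(path)
    fasta_records = list(SeqIO.parse(str(path), "fasta"))
    if not fasta_records:
        raise FormatError(f"'{path}' contains no FASTA records")

    ids = [rec.id for rec in fasta_records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise FormatError(f"duplicate sequence ids in '{path}': {', '.join(dupes)}")

    records = []
    for rec in fasta_records:
        desc = rec.description
        product = desc[len(rec.id):].strip() if desc.startswith(rec.id) else desc
        records.append(
            ProteinRecord(
                protein_id=rec.id,
                genome_id=genome_id,
                sequence=str(rec.seq),
                product=product,
            )
        )
    return Proteome(genome_id=genome_id, records=records)


def write_fasta(proteome: Proteome | Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records as FASTA (id + product on the header line)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in proteome:
            header = rec.protein_id if not rec.product else f"{rec.protein_id} {rec.product}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Result persistence
# ---------------------------------------------------------------------------

_SAFE_ID = re.compile(r"[^A-Za-z0-9_.-]")


def _result_filename(protein_id: str, method: str) -> str:
    safe = _SAFE_ID.sub("_", protein_id)
    return f"{safe}__{method}.csv"


def empty_results() -> pd.DataFrame:
    """An empty prediction-result table with the standard columns."""
    return pd.DataFrame(
        {
            "protein_id": pd.Series(dtype=str),
            "method": pd.Series(dtype=str),
            "allele": pd.Series(dtype=str),
            "start": pd.Series(dtype=int),
            "peptide": pd.Series(dtype=str),
            "score": pd.Series(dtype=float),
        }
    )


def validate_results(result: pd.DataFrame) -> pd.DataFrame:
    """Check a result table has the standard columns in order; return it."""
    if tuple(result.columns) != RESULT_COLUMNS:
        raise ValueError(
            f"result table must have columns {list(RESULT_COLUMNS)}, "
            f"got {list(result.columns)}"
        )
    return result


def write_results(result: pd.DataFrame, directory: str | Path) -> list[Path]:
    """Persist a result table as one CSV per (protein, method).

    Scores are serialized at full float precision so that
    ``read_results(write_results(x))`` reproduces every row exactly.
    Returns the list of files written.
    """
    validate_results(result)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for (protein_id, method), group in result.groupby(["protein_id", "method"], sort=False):
        target = directory / _result_filename(str(protein_id), str(method))
        group.to_csv(target, index=False)
        written.append(target)
    return written


def _read_result_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"protein_id": str, "method": str, "allele": str, "peptide": str},
        float_precision="round_trip",
    )
    df["start"] = df["start"].astype(int)
    df["score"] = df["score"].astype(float)
    return validate_results(df[list(RESULT_COLUMNS)])


def read_results(directory: str | Path, protein_id: str, method: str | None = None) -> pd.DataFrame:
    """Load the persisted results for one protein (all methods by default)."""
    directory = Path(directory)
    safe = _SAFE_ID.sub("_", protein_id)
    pattern = f"{safe}__{method}.csv" if method else f"{safe}__*.csv"
    files = sorted(directory.glob(pattern))
    if not files:
        raise FileNotFoundError(
            f"no stored results for protein '{protein_id}' in '{directory}'"
        )
    return pd.concat([_read_result_csv(f) for f in files], ignore_index=True)


def read_all_results(directory: str | Path) -> pd.DataFrame:
    """Load every persisted result CSV in a directory (empty table if none)."""
    directory = Path(directory)
    files = sorted(directory.glob("*__*.csv"))
    if not files:
        return empty_results()
    return pd.concat([_read_result_csv(f) for f in files], ignore_index=True)


# ---------------------------------------------------------------------------
# Synthetic-data generators
# ---------------------------------------------------------------------------

def generate_random_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (100, 500),
    aa_freqs: Sequence[float] | None = None,
    seed: int = 0,
    genome_id: str = "synthetic",
) -> Proteome:
    """Generate a random proteome with i.i.d. residues.

    Lengths are uniform on ``[min, max]`` and residues are drawn i.i.d.
    from ``aa_freqs`` (a 20-vector over :data:`AA_ALPHABET`; uniform by
    default).  Deterministic for a fixed ``seed``.  Protein ids are
    ``SYN0001``-style.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    if lo < 9:
        raise ValueError("minimum protein length must be >= 9 (the scan window)")
    if hi < lo:
        raise ValueError("length_range must satisfy min <= max")
    if aa_freqs is None:
        freqs = np.full(20, 0.05)
    else:
        freqs = np.asarray(aa_freqs, dtype=float)
        if freqs.shape != (20,):
            raise ValueError("aa_freqs must have 20 entries")
        if (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("aa_freqs must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(AA_ALPHABET.encode(), dtype="S1")
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(alphabet, size=length, p=freqs).tobytes().decode()
        records.append(
            ProteinRecord(
                protein_id=f"SYN{i + 1:04d}",
                genome_id=genome_id,
                sequence=seq,
                product="synthetic protein",
            )
        )
    return Proteome(genome_id=genome_id, records=records)


def plant_epitopes(
    proteome: Proteome,
    motif: str,
    carrier_ids: Iterable[str],
    copies_per_carrier: int = 1,
    seed: int = 0,
) -> tuple[Proteome, dict[str, list[int]]]:
    """Overwrite random non-overlapping positions of carrier proteins with a 9-mer motif.

    Returns the modified proteome copy and a map from carrier id to the
    1-based planted start positions (sorted).  Non-carrier proteins are
    untouched.  Raises if a carrier is too short to host the requested
    number of non-overlapping copies.
    """
    motif = _check_sequence(motif, "motif")
    if len(motif) != 9:
        raise ValueError("motif must be a 9-mer")
    if copies_per_carrier < 1:
        raise ValueError("copies_per_carrier must be >= 1")
    carriers = list(carrier_ids)
    known = set(proteome.protein_ids)
    missing = [c for c in carriers if c not in known]
    if missing:
        raise ValueError(f"carrier ids not in proteome: {', '.join(missing)}")

    rng = np.random.default_rng(seed)
    placements: dict[str, list[int]] = {}
    new_records = []
    carrier_set = set(carriers)
    for rec in proteome:
        if rec.protein_id not in carrier_set:
            new_records.append(rec)
            continue
        L = len(rec)
        candidates = rng.permutation(max(0, L - 8))  # 0-based starts
        chosen: list[int] = []
        for s in candidates:
            s = int(s)
            if all(abs(s - t) >= 9 for t in chosen):
                chosen.append(s)
                if len(chosen) == copies_per_carrier:
                    break
        if len(chosen) < copies_per_carrier:
            raise ValueError(
                f"carrier '{rec.protein_id}' (length {L}) cannot host "
                f"{copies_per_carrier} non-overlapping 9-mer copies"
            )
        seq = list(rec.sequence)
        for s in chosen:
            seq[s : s + 9] = motif
        new_records.append(
            ProteinRecord(
                protein_id=rec.protein_id,
                genome_id=rec.genome_id,
                sequence="".join(seq),
                product=rec.product,
                gene=rec.gene,
            )
        )
        placements[rec.protein_id] = sorted(s + 1 for s in chosen)
    return Proteome(genome_id=proteome.genome_id, records=new_records), placements


def generate_ortholog_set(
    query: ProteinRecord,
    n_subjects: int,
    mu: float,
    seed: int = 0,
) -> OrthologSet:
    """Simulate orthologs by i.i.d. per-site substitution of the query.

    Each subject is a copy of the query sequence in which every site is
    independently replaced, with probability ``mu``, by a uniformly
    random *different* residue.  The percent identity of each subject to
    the query is computed with
    :func:`epitopescan.conservation.pairwise_identity`.
    """
    from .conservation import pairwise_identity  # local import: avoids a cycle

    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")

    rng = np.random.default_rng(seed)
    qseq = np.frombuffer(query.sequence.encode(), dtype="S1")
    alphabet = np.frombuffer(AA_ALPHABET.encode(), dtype="S1")
    subjects = []
    for i in range(n_subjects):
        mutate = rng.random(len(qseq)) < mu
        seq = qseq.copy()
        if mutate.any():
            # draw a uniformly random different residue per mutated site
            for pos in np.flatnonzero(mutate):
                choices = alphabet[alphabet != qseq[pos]]
                seq[pos] = rng.choice(choices)
        s = seq.tobytes().decode()
        subjects.append(
            OrthologSubject(
                subject_id=f"ORTH{i + 1:04d}",
                sequence=s,
                percent_identity_to_query=pairwise_identity(query.sequence, s),
            )
        )
    return OrthologSet(query=query, subjects=subjects)


def write_ortholog_fasta(oset: OrthologSet, path: str | Path, include_query: bool = True) -> None:
    """Write an ortholog set as FASTA; the query record comes first."""
    path = Path(path)
    with path.open("w") as fh:
        if include_query:
            fh.write(f">{oset.query.protein_id} query\n{oset.query.sequence}\n")
        for sub in oset.subjects:
            fh.write(f">{sub.subject_id}\n{sub.sequence}\n")
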