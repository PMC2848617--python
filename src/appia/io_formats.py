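"""Readers and writers for every external format the pipeline touches.

Conventions
-----------
* Genomic coordinates are GFF3-style throughout: 1-based and inclusive at
  both ends.  No BED-style half-open intervals anywhere.
* A pair of protein identifiers is always stored canonically, i.e. as a
  tuple ``(a, b)`` with ``a < b`` lexicographically.  Homodimers are not
  representable.
* The species identifier of an alignment row is the first
  whitespace-delimited token of the FASTA header and must match the genome
  identifiers used in the ortholog table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1

#: feature types of a GFF3 file that carry gene coordinates
GFF_GENE_TYPES = frozenset({"gene", "CDS"})


class FormatError(ValueError):
    """An input file violates its documented grammar."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the pair ``(a, b)`` in canonical (lexicographic) order.

    Raises ``ValueError`` for homodimers, which are not representable.
    """
    if a == b:
        raise ValueError(f"homodimer pair ({a!r}, {a!r}) is not representable")
    return (a, b) if a < b else (b, a)


# ---------------------------------------------------------------------------
# Ortholog tables
# ---------------------------------------------------------------------------

@dataclass
class OrthologTable:
    """Per-protein, per-genome ortholog assignments.

    ``entries`` maps ``(protein, genome)`` to the identifier of the ortholog
    gene in that genome.  Absent entries mean "no ortholog detected".
    """

    genomes: list[str]
    proteins: list[str]
    entries: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genomes)) != len(self.genomes):
            raise FormatError("duplicate genome identifiers in ortholog table")
        if len(set(self.proteins)) != len(self.proteins):
            raise FormatError("duplicate protein identifiers in ortholog table")
        genome_set = set(self.genomes)
        protein_set = set(self.proteins)
        for protein, genome in self.entries:
            if genome not in genome_set:
                raise FormatError(f"entry references unknown genome {genome!r}")
            if protein not in protein_set:
                raise FormatError(f"entry references unknown protein {protein!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def orthologs_of(self, protein: str) -> dict[str, str]:
        """Genome -> ortholog gene id for one protein, in genome order."""
        out = {}
        for genome in self.genomes:
            gene = self.entries.get((protein, genome))
            if gene is not None:
                out[genome] = gene
        return out

    def n_orthologs(self, protein: str) -> int:
        return sum(1 for g in self.genomes if (protein, g) in self.entries)


def read_ortholog_table(path: str | Path) -> OrthologTable:
    """Read a TSV ortholog table: header ``protein<TAB>genome1<TAB>...``.

    One row per protein; empty cells become absent entries.
    """
    path = Path(path)
    with path.open() as handle:
        header = handle.readline()
        if not header.strip():
            raise FormatError(f"{path}: missing header row")
        columns = header.rstrip("\n").split("\t")
        genomes = columns[1:]
        if len(set(genomes)) != len(genomes):
            raise FormatError(f"{path}: duplicate genome columns in header")
        proteins: list[str] = []
        seen: set[str] = set()
        entries: dict[tuple[str, str], str] = {}
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) > len(columns):
                raise FormatError(f"{path}:{lineno}: more cells than header columns")
            protein = cells[0]
            if protein in seen:
                raise FormatError(f"{path}:{lineno}: duplicate protein row {protein!r}")
            seen.add(protein)
            proteins.append(protein)
            for genome, cell in zip(genomes, cells[1:]):
                if cell:
                    entries[(protein, genome)] = cell
    return OrthologTable(genomes=genomes, proteins=proteins, entries=entries)


def write_ortholog_table(table: OrthologTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as handle:
        handle.write("protein\t" + "\t".join(table.genomes) + "\n")
        for protein in table.proteins:
            cells = [table.entries.get((protein, g), "") for g in table.genomes]
            handle.write(protein + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Gene coordinates (GFF3)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneLocation:
    """1-based inclusive location of a gene on a contig."""

    genome: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise FormatError(f"start {self.start} < 1")
        if self.start > self.end:
            raise FormatError(f"start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise FormatError(f"invalid strand {self.strand!r}")


def _gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gene_coordinates(
    path: str | Path,
    genome: str | None = None,
    feature_types: frozenset[str] = GFF_GENE_TYPES,
) -> dict[tuple[str, str], GeneLocation]:
    """Read gene coordinates from a GFF3 file.

    Returns a map ``(genome, gene id) -> GeneLocation``.  The genome id
    defaults to the file name stem.  Records without an ``ID`` attribute are
    skipped with a logged warning; ``end < start`` is a format error.
    """
    path = Path(path)
    if genome is None:
        genome = path.stem
    out: dict[tuple[str, str], GeneLocation] = {}
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cells)}")
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cells
            if ftype not in feature_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            gene_id = _gff_attributes(attrs).get("ID")
            if gene_id is None:
                log.warning("%s:%d: feature without ID attribute skipped", path, lineno)
                continue
            try:
                location = GeneLocation(genome, contig, start, end, strand)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out[(genome, gene_id)] = location
    return out


def read_gene_coordinates_dir(directory: str | Path) -> dict[tuple[str, str], GeneLocation]:
    """Merge the coordinates of every ``*.gff3`` file in a directory."""
    merged: dict[tuple[str, str], GeneLocation] = {}
    for path in sorted(Path(directory).glob("*.gff3")):
        merged.update(read_gene_coordinates(path))
    return merged


def write_gene_coordinates(
    locations: Mapping[tuple[str, str], GeneLocation], path: str | Path
) -> None:
    """Write one genome's gene coordinates as GFF3 (sorted by position)."""
    records = sorted(locations.items(), key=lambda kv: (kv[1].contig, kv[1].start, kv[0]))
    with Path(path).open("w") as handle:
        handle.write("##gff-version 3\n")
        for (_genome, gene_id), loc in records:
            handle.write(
                f"{loc.contig}\t.\tgene\t{loc.start}\t{loc.end}\t.\t{loc.strand}\t.\tID={gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Ortholog alignments (aligned FASTA)
# ---------------------------------------------------------------------------

@dataclass
class OrthologAlignment:
    """One protein's orthologs, aligned.  Rows map species id -> gapped sequence."""

    protein: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError(f"alignment for {self.protein!r} has no rows")
        lengths = {len(seq) for seq in self.rows.values()}
        if len(lengths) != 1:
            raise FormatError(
                f"alignment for {self.protein!r} is ragged: row lengths {sorted(lengths)}"
            )

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))


def read_alignment(path: str | Path, protein: str | None = None) -> OrthologAlignment:
    """Read an aligned FASTA file; species id = first header token."""
    path = Path(path)
    if protein is None:
        protein = path.stem
    rows: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        species = record.id.split()[0]
        if species in rows:
            raise FormatError(f"{path}: duplicate species header {species!r}")
        rows[species] = str(record.seq)
    return OrthologAlignment(protein=protein, rows=rows)


def write_alignment(alignment: OrthologAlignment, path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for species, seq in alignment.rows.items():
            handle.write(f">{species}\n{seq}\n")


def read_alignment_dir(directory: str | Path) -> dict[str, OrthologAlignment]:
    out = {}
    for path in sorted(Path(directory).glob("*.fasta")):
        out[path.stem] = read_alignment(path)
    return out


# ---------------------------------------------------------------------------
# Pair lists
# ---------------------------------------------------------------------------

class PairList:
    """A set of canonical, unordered protein pairs with source tags and scores."""

    def __init__(self) -> None:
        self._sources: dict[tuple[str, str], set[str]] = {}
        self._scores: dict[tuple[str, str], float] = {}
        self.dropped_homodimers = 0

    def add(
        self,
        a: str,
        b: str,
        source: str | None = None,
        score: float | None = None,
    ) -> None:
        """Add a pair; homodimers are dropped (and counted), duplicates merged.

        When a duplicate arrives with a different score the maximum is kept.
        """
        if a == b:
            self.dropped_homodimers += 1
            return
        pair = canonical_pair(a, b)
        tags = self._sources.setdefault(pair, set())
        if source is not None:
            tags.add(source)
        if score is not None:
            if pair in self._scores and self._scores[pair] != score:
                log.info("duplicate pair %s with different scores; keeping maximum", pair)
                self._scores[pair] = max(self._scores[pair], score)
            else:
                self._scores[pair] = score

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self._sources)

    def sources_of(self, pair: tuple[str, str]) -> frozenset[str]:
        return frozenset(self._sources[pair])

    def score_of(self, pair: tuple[str, str]) -> float | None:
        return self._scores.get(pair)

    @property
    def scores(self) -> dict[tuple[str, str], float]:
        return dict(self._scores)

    def proteins(self) -> set[str]:
        return {p for pair in self._sources for p in pair}

    def update(self, other: "PairList") -> None:
        for pair, tags in other._sources.items():
            self._sources.setdefault(pair, set()).update(tags)
        for pair, score in other._scores.items():
            self.add(pair[0], pair[1], score=score)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._sources

    def __len__(self) -> int:
        return len(self._sources)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self._sources))


def read_pair_list(path: str | Path, source: str | None = None) -> PairList:
    """Read a TSV pair list with columns ``idA<TAB>idB[<TAB>score]``.

    Pairs are canonicalized; homodimer rows are dropped and counted.
    Malformed rows raise :class:`FormatError` with the line number.
    """
    path = Path(path)
    pairs = PairList()
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) == 2:
                a, b = cells
                score = None
            elif len(cells) == 3:
                a, b = cells[0], cells[1]
                try:
                    score = float(cells[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score {cells[2]!r}") from exc
            else:
                raise FormatError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(cells)}")
            if not a or not b:
                raise FormatError(f"{path}:{lineno}: empty protein id")
            pairs.add(a, b, source=source, score=score)
    if pairs.dropped_homodimers:
        log.info("%s: dropped %d homodimer rows", path, pairs.dropped_homodimers)
    return pairs


def read_tagged_pair_list(path: str | Path) -> PairList:
    """Read a TSV pair list whose third column is a source tag
    (``idA<TAB>idB[<TAB>source]``)."""
    path = Path(path)
    pairs = PairList()
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) not in (2, 3):
                raise FormatError(f"{path}:{lineno}: expected 2 or 3 columns")
            source = cells[2] if len(cells) == 3 else "unspecified"
            pairs.add(cells[0], cells[1], source=source)
    return pairs


def write_pair_list(pairs: PairList, path: str | Path, with_scores: bool = False) -> None:
    with Path(path).open("w") as handle:
        for a, b in pairs:
            if with_scores:
                score = pairs.score_of((a, b))
                handle.write(f"{a}\t{b}\t{score}\n")
            else:
                handle.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Pair-score TSV (internal method-output format: idA, idB, method, score)
# ---------------------------------------------------------------------------

SCORE_COLUMNS = ["protein_a", "protein_b", "method", "score"]


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str, 1: str, 2: str, 3: float})
    if list(df.columns) != SCORE_COLUMNS:
        raise FormatError(f"{path}: expected columns {SCORE_COLUMNS}, got {list(df.columns)}")
    return df


def write_scores(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=SCORE_COLUMNS)


# ---------------------------------------------------------------------------
# Protein tables and regulons
# ---------------------------------------------------------------------------

def read_protein_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV ``protein<TAB>length`` (header optional)."""
    out: dict[str, int] = {}
    with Path(path).open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and cells[0] == "protein":
                continue
            try:
                out[cells[0]] = int(cells[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer length") from exc
    return out


def write_protein_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        handle.write("protein\tlength\n")
        for protein in sorted(lengths):
            handle.write(f"{protein}\t{lengths[protein]}\n")


def read_regulons(path: str | Path) -> dict[str, set[str]]:
    """Read a regulon TSV ``regulator<TAB>target``."""
    out: dict[str, set[str]] = {}
    with Path(path).open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            out.setdefault(cells[0], set()).add(cells[1])
    return out


def write_regulons(regulons: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for regulator in sorted(regulons):
            for target in sorted(regulons[regulator]):
                handle.write(f"{regulator}\t{target}\n")


# ---------------------------------------------------------------------------
# Model serialization (JSON, versioned)
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path) -> None:
    """Serialize a trained classifier to versioned JSON.

    The model object must expose ``to_json_dict()``; an untrained or empty
    model (fewer than two classes) is an error.
    """
    payload = model.to_json_dict()
    if len(payload.get("classes", [])) < 2:
        raise ValueError("refusing to save a model with fewer than two classes")
    payload["schema_version"] = MODEL_SCHEMA_VERSION
    with Path(path).open("w") as handle:
        json.dump(payload, handle)


def load_model(path: str | Path):
    from . import aode  # local import: aode has no dependency on this module

    try:
        with Path(path).open() as handle:
            payload = json.load(handle)
    except (json.JSONDecodeError, OSError) as exc:
        raise FormatError(f"{path}: unreadable model file: {exc}") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise FormatError(
            f"{path}: model schema version {version!r} != supported {MODEL_SCHEMA_VERSION}"
        )
    return aode.AODEModel.from_json_dict(payload)
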