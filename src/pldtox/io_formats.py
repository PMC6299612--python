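"""Readers/writers for the standard formats the pipeline touches.

FASTA carries the protein records, 12-column tabular files carry similarity-search
hits, Newick carries rooted (possibly multifurcating) species and gene trees, and
simple TSV carries presence/absence matrices and reports.  Open-reading-frame
inference supports hits found in nucleotide (transcript) data.

Conventions used throughout the package:

* coordinates are 1-based and inclusive, matching the tabular search format;
* a taxon is an ordered lineage path (root-most rank first), e.g.
  ``["Eukaryota", "Arthropoda", "Chelicerata"]``; comparisons between lineages
  are made at a fixed rank index (prefix comparison);
* sequence alphabets: proteins use the 20 standard residues plus ``X``,
  nucleotides use ``ACGTN``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "HitRecord",
    "SpeciesTree",
    "Orf",
    "FastaFormatError",
    "HitTableFormatError",
    "NewickFormatError",
    "read_fasta",
    "write_fasta",
    "read_hits_tabular",
    "write_hits_tabular",
    "read_newick",
    "write_newick",
    "read_presence_matrix",
    "find_orfs",
    "PROTEIN_ALPHABET",
]

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
_DNA_ALPHABET = frozenset("ACGTN")

# Evidence categories recognised for the two-data-type confidence rule.
EVIDENCE_TYPES = frozenset({"genome", "transcriptome", "EST", "proteome"})


class FastaFormatError(ValueError):
    """Malformed FASTA input (duplicate ids, empty sequences, bad residues)."""


class HitTableFormatError(ValueError):
    """Malformed 12-column tabular similarity-search input."""


class NewickFormatError(ValueError):
    """Malformed Newick input."""


@dataclass
class SequenceRecord:
    """One protein (or translated) sequence with lineage and provenance.

    Parameters
    ----------
    id:
        Unique accession-like identifier.
    residues:
        Amino-acid string over the 20 standard residues plus ``X``.
    taxon:
        Ordered lineage path, root-most rank first.  May be empty (unknown).
    evidence:
        Data types supporting the record, drawn from
        ``{genome, transcriptome, EST, proteome}``.  May be empty (unknown).
    source_note:
        Free-text provenance note.
    """

    id: str
    residues: str
    taxon: tuple[str, ...] = ()
    evidence: frozenset[str] = frozenset()
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        if not self.residues:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise FastaFormatError(
                f"record {self.id!r} contains invalid residues: {sorted(bad)}"
            )
        self.taxon = tuple(self.taxon)
        self.evidence = frozenset(self.evidence)
        unknown = self.evidence - EVIDENCE_TYPES
        if unknown:
            raise ValueError(f"unknown evidence types {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.residues)

    def rank(self, index: int) -> str | None:
        """Lineage name at rank ``index`` (0 = root-most) or None if unknown."""
        return self.taxon[index] if index < len(self.taxon) else None


@dataclass
class HitRecord:
    """One similarity-search hit row (standard 12-column tabular format).

    ``query_span`` and ``subject_span`` are 1-based inclusive.  ``query_length``
    is taken from a side table of query lengths and may be None when the query
    is unknown there, in which case coverage is undefined.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    evalue: float
    bitscore: float
    query_length: int | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue}")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(f"percent identity {self.percent_identity} outside 0-100")
        if self.alignment_length < 1:
            raise ValueError("alignment length must be >= 1")
        for name, (start, end) in (
            ("query", self.query_span),
            ("subject", self.subject_span),
        ):
            if start < 1 or end < start:
                raise ValueError(f"invalid {name} span {start}-{end}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(
    r"^(?P<id>\S+)"
    r"(?P<desc>[^\[\{]*?)"
    r"(?:\s*\[(?P<taxon>[^\]]*)\])?"
    r"(?:\s*\{(?P<evidence>[^\}]*)\})?"
    r"\s*$"
)


def _parse_header(header: str) -> SequenceRecord | None:
    """Split a FASTA header into id / note / lineage / evidence parts."""
    m = _HEADER_RE.match(header)
    if m is None:  # pragma: no cover - regex accepts any non-empty token
        raise FastaFormatError(f"unparseable FASTA header: {header!r}")
    taxon = tuple(
        t.strip() for t in (m.group("taxon") or "").split(";") if t.strip()
    )
    evidence = frozenset(
        e.strip() for e in (m.group("evidence") or "").split(",") if e.strip()
    )
    return m.group("id"), (m.group("desc") or "").strip(), taxon, evidence


def read_fasta(stream) -> list[SequenceRecord]:
    """Parse FASTA into :class:`SequenceRecord` objects, order preserved.

    The first header token is the id; an optional trailing ``[a; b; c]`` block
    is parsed as the ordered lineage and an optional ``{genome,transcriptome}``
    block as the evidence set.  Duplicate ids and empty sequences are errors.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        rec_id, note, taxon, evidence = _parse_header(header)
        if rec_id in seen:
            raise FastaFormatError(f"duplicate sequence id {rec_id!r}")
        seen.add(rec_id)
        records.append(
            SequenceRecord(
                id=rec_id,
                residues="".join(chunks).upper(),
                taxon=taxon,
                evidence=evidence,
                source_note=note,
            )
        )

    for line in stream:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            if not header:
                raise FastaFormatError("FASTA header with no id")
            chunks = []
        else:
            if header is None:
                raise FastaFormatError("sequence data before first FASTA header")
            chunks.append(line.strip())
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], stream=None, width: int = 60) -> str:
    """Write records as FASTA; returns the text (also written to ``stream``)."""
    out = io.StringIO()
    for rec in records:
        header = rec.id
        if rec.source_note:
            header += f" {rec.source_note}"
        if rec.taxon:
            header += f" [{'; '.join(rec.taxon)}]"
        if rec.evidence:
            header += f" {{{','.join(sorted(rec.evidence))}}}"
        out.write(f">{header}\n")
        for i in range(0, len(rec.residues), width):
            out.write(rec.residues[i : i + width] + "\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# 12-column tabular hits
# ---------------------------------------------------------------------------

def read_hits_tabular(stream, query_lengths: dict[str, int] | None = None) -> list[HitRecord]:
    """Parse the standard 12-column tab-separated similarity-search output.

    Columns: query, subject, %identity, alignment length, mismatches, gap
    opens, q.start, q.end, s.start, s.end, E-value, bitscore.  Rows are kept in
    input order.  ``query_lengths`` maps query id -> length; queries missing
    from it are tolerated (their coverage is undefined downstream).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    query_lengths = query_lengths or {}
    hits: list[HitRecord] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise HitTableFormatError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        try:
            hit = HitRecord(
                query_id=fields[0],
                subject_id=fields[1],
                percent_identity=float(fields[2]),
                alignment_length=int(fields[3]),
                mismatches=int(fields[4]),
                gap_opens=int(fields[5]),
                query_span=(int(fields[6]), int(fields[7])),
                subject_span=(int(fields[8]), int(fields[9])),
                evalue=float(fields[10]),
                bitscore=float(fields[11]),
                query_length=query_lengths.get(fields[0]),
            )
        except ValueError as exc:
            raise HitTableFormatError(f"line {lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def write_hits_tabular(hits: Iterable[HitRecord], stream=None) -> str:
    out = io.StringIO()
    for h in hits:
        out.write(
            "\t".join(
                str(x)
                for x in (
                    h.query_id,
                    h.subject_id,
                    f"{h.percent_identity:.2f}",
                    h.alignment_length,
                    h.mismatches,
                    h.gap_opens,
                    h.query_span[0],
                    h.query_span[1],
                    h.subject_span[0],
                    h.subject_span[1],
                    f"{h.evalue:.3g}",
                    f"{h.bitscore:.1f}",
                )
            )
            + "\n"
        )
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

class SpeciesTree:
    """Rooted tree with named tips; polytomies permitted.

    Thin wrapper around a :class:`dendropy.Tree` enforcing the package's
    invariants: exactly one root, unique tip names, and no internal node with a
    single child (unifurcations are suppressed on construction).
    """

    def __init__(self, tree: dendropy.Tree):
        tree.suppress_unifurcations()
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickFormatError(f"duplicate tip names: {dupes}")
        self._tips = tuple(labels)

    # -- construction -------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:
            raise NewickFormatError(f"Newick parse error: {exc}") from exc
        if not tree.leaf_nodes():
            raise NewickFormatError("tree has no tips")
        tree.is_rooted = True
        return cls(tree)

    def to_newick(self) -> str:
        text = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_edge_lengths=not self.has_branch_lengths,
        )
        return text.strip() + ("" if text.strip().endswith(";") else ";")

    # -- structure ----------------------------------------------------------
    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def tip_names(self) -> tuple[str, ...]:
        return self._tips

    @property
    def has_branch_lengths(self) -> bool:
        return any(
            e.length is not None for e in self._tree.preorder_edge_iter()
        )

    def __len__(self) -> int:
        return len(self._tips)

    def nodes(self):
        return self._tree.preorder_node_iter()

    def internal_nodes(self):
        return [n for n in self.nodes() if not n.is_leaf()]

    def leaf_set(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def node_label(self, node: dendropy.Node) -> str | None:
        if node.is_leaf():
            return node.taxon.label
        return node.label

    def find_node(self, label: str) -> dendropy.Node:
        """Locate a node by tip name or internal label."""
        for node in self.nodes():
            if self.node_label(node) == label:
                return node
        raise KeyError(f"no node labelled {label!r}")

    def mrca(self, tip_names: Iterable[str]) -> dendropy.Node:
        names = set(tip_names)
        missing = names - set(self._tips)
        if missing:
            raise KeyError(f"unknown tip names: {sorted(missing)}")
        if len(names) == 1:
            (name,) = names
            return self._tree.find_node_with_taxon_label(name)
        return self._tree.mrca(taxon_labels=sorted(names))


def read_newick(text: str) -> SpeciesTree:
    """Parse a Newick string into a :class:`SpeciesTree`."""
    return SpeciesTree.from_newick(text)


def write_newick(tree: SpeciesTree) -> str:
    return tree.to_newick()


def read_presence_matrix(stream) -> "pd.DataFrame":
    """Read a TSV presence/absence matrix (rows = taxa, columns = families).

    Entries are ``present``/``absent``/``unknown`` (also accepts 1/0/?).
    """
    import pandas as pd

    if isinstance(stream, str) and "\t" not in stream and "\n" not in stream:
        df = pd.read_csv(stream, sep="\t", index_col=0, dtype=str)
    else:
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        df = pd.read_csv(stream, sep="\t", index_col=0, dtype=str)
    mapping = {
        "present": "present", "1": "present",
        "absent": "absent", "0": "absent",
        "unknown": "unknown", "?": "unknown",
    }

    def norm(v: str) -> str:
        key = str(v).strip().lower()
        if key not in mapping:
            raise ValueError(f"invalid presence state {v!r}")
        return mapping[key]

    return df.map(norm)


# ---------------------------------------------------------------------------
# ORF inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Orf:
    """A translated open reading frame.

    ``start``/``end`` are 1-based inclusive nucleotide coordinates on the
    *input* strand (start < end even for minus-strand ORFs); ``frame`` is
    +1..+3 or -1..-3.
    """

    peptide: str
    frame: int
    start: int
    end: int

    @property
    def strand(self) -> int:
        return 1 if self.frame > 0 else -1


def find_orfs(
    nucleotide_sequence: str,
    min_aa_length: int = 1,
    *,
    allow_partial: bool = False,
) -> list[Orf]:
    """Infer open reading frames in all six frames of a DNA sequence.

    An ORF runs from a Met codon to the next stop codon (stop excluded from the
    peptide).  Within a stop-bounded segment only the longest (first-Met) ORF
    is reported.  With ``allow_partial`` ORFs truncated by the sequence edge
    are also reported: a segment running off the 3' end needs no stop, and a
    segment beginning at the 5' edge of its frame needs no Met.

    Results are sorted by peptide length descending (ties by coordinates).
    """
    seq = nucleotide_sequence.upper()
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters in input: {sorted(bad)}")
    n = len(seq)
    orfs: list[Orf] = []

    for strand, strand_seq in ((1, seq), (-1, str(Seq(seq).reverse_complement()))):
        for offset in range(3):
            frame = strand * (offset + 1)
            # split the frame translation into stop-bounded segments
            # (trim to whole codons; a trailing partial codon cannot code)
            frame_seq = strand_seq[offset : offset + 3 * ((n - offset) // 3)]
            aa = str(Seq(frame_seq).translate())
            pos = 0
            for segment in aa.split("*"):
                seg_start = pos  # aa index of segment start within frame
                pos += len(segment) + 1
                has_stop = seg_start + len(segment) < len(aa)
                at_5_edge = seg_start == 0
                m = segment.find("M")
                if m >= 0 and (has_stop or allow_partial):
                    _emit(orfs, segment[m:], frame, offset, seg_start + m, strand, n)
                if (
                    allow_partial
                    and at_5_edge
                    and segment
                    and m != 0
                ):
                    # 5'-truncated reading: no Met requirement at the edge
                    _emit(orfs, segment, frame, offset, seg_start, strand, n)
    orfs = [o for o in orfs if len(o.peptide) >= min_aa_length]
    orfs.sort(key=lambda o: (-len(o.peptide), o.start, o.frame))
    return orfs


def _emit(
    orfs: list[Orf],
    peptide: str,
    frame: int,
    offset: int,
    aa_start: int,
    strand: int,
    n: int,
) -> None:
    if not peptide or set(peptide) == {"X"}:
        return
    nt_start = offset + 3 * aa_start  # 0-based on the reading strand
    nt_end = nt_start + 3 * len(peptide) - 1
    if strand == 1:
        start, end = nt_start + 1, nt_end + 1
    else:
        start, end = n - nt_end, n - nt_start
    orfs.append(Orf(peptide=peptide, frame=frame, start=start, end=end))
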