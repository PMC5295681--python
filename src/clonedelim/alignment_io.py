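"""Alignment and metadata I/O, haplotype collapsing, translation, and
lineage-diagnostic substitution screening.

Sequences are kept as plain upper-case strings over the DNA alphabet
(including gaps ``-`` and IUPAC ambiguity letters).  Haplotype identity is
*literal* string equality — two sequences differing only at an ``N`` versus
``A`` position are distinct haplotypes — which reproduces the counting
convention of standard haplotype-collapsing tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENETIC_CODES = {
    "standard": 1,
    "invertebrate_mito": 5,
    "none": None,
}

#: characters excluded from site comparisons (alongside anything non-ACGT
#: being excluded from model-based computations)
MISSING_CHARS = frozenset("-N?")

DNA_ALPHABET = frozenset("ACGTRYSWKMBDHVN-?")


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignment input."""


@dataclass
class Alignment:
    """A multiple sequence alignment for a single locus.

    Parameters
    ----------
    locus_name : str
        Identifier of the locus (e.g. ``"COI"``).
    sample_ids : list of str
        Unique sample identifiers, one per sequence.
    sequences : list of str
        Equal-length aligned sequences, upper case.
    coding : bool
        Whether the locus is protein coding (enables translation and
        codon-position operations).
    genetic_code_id : {"standard", "invertebrate_mito", "none"}
        Translation table for coding loci.
    frame_offset : int
        0-based offset of the first complete codon (0, 1 or 2).
    is_protein : bool
        True for amino-acid alignments produced by :func:`translate`.
    """

    locus_name: str
    sample_ids: list[str]
    sequences: list[str]
    coding: bool = False
    genetic_code_id: str = "none"
    frame_offset: int = 0
    is_protein: bool = False

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError("sample_ids and sequences length mismatch")
        if not self.sequences:
            raise AlignmentError(f"alignment '{self.locus_name}' is empty")
        L = len(self.sequences[0])
        for sid, seq in zip(self.sample_ids, self.sequences):
            if len(seq) != L:
                raise AlignmentError(
                    f"ragged alignment '{self.locus_name}': record '{sid}' has "
                    f"length {len(seq)}, expected {L}"
                )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            raise AlignmentError(f"duplicate sample ids: {sorted(dupes)}")
        if self.coding and self.genetic_code_id == "none":
            raise AlignmentError("coding alignment requires a genetic code id")
        if self.genetic_code_id not in GENETIC_CODES:
            raise AlignmentError(f"unknown genetic code '{self.genetic_code_id}'")
        if self.frame_offset not in (0, 1, 2):
            raise AlignmentError("frame_offset must be 0, 1 or 2")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def sequence_of(self, sample_id: str) -> str:
        return self.sequences[self.sample_ids.index(sample_id)]

    def subset(self, sample_ids: Sequence[str]) -> "Alignment":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise AlignmentError(f"samples not in alignment: {missing}")
        return replace(
            self,
            sample_ids=list(sample_ids),
            sequences=[self.sequences[idx[s]] for s in sample_ids],
        )


@dataclass
class HaplotypeTable:
    """Grouping of samples into identical-sequence classes.

    ``haplotype_ids`` are ordered by first occurrence in the source
    alignment; ``members`` maps each haplotype id to the sample ids that
    carry it, and ``representative`` to the shared sequence.
    """

    level: str  # "nucleotide" or "amino_acid"
    haplotype_ids: list[str] = field(default_factory=list)
    members: dict[str, list[str]] = field(default_factory=dict)
    representative: dict[str, str] = field(default_factory=dict)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    def haplotype_of(self) -> dict[str, str]:
        """Map sample id -> haplotype id."""
        out: dict[str, str] = {}
        for hid, mem in self.members.items():
            for s in mem:
                out[s] = hid
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"haplotype_id": h, "n_members": len(self.members[h]),
             "member_sample_ids": ",".join(self.members[h])}
            for h in self.haplotype_ids
        ]
        return pd.DataFrame(rows)


@dataclass
class LineagePartition:
    """Assignment of samples to groups (lineages or sampling locations)."""

    group_of: dict[str, str]
    grouping_kind: str = "lineage"

    def __post_init__(self) -> None:
        if not self.group_of:
            raise ValueError("empty partition")

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, g in self.group_of.items():
            out.setdefault(g, []).append(s)
        return out

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for g in self.group_of.values():
            if g not in seen:
                seen.append(g)
        return sorted(seen)

    def restrict(self, sample_ids: Iterable[str]) -> "LineagePartition":
        sub = {s: self.group_of[s] for s in sample_ids}
        return LineagePartition(sub, self.grouping_kind)


# ---------------------------------------------------------------------------
# FASTA / metadata I/O
# ---------------------------------------------------------------------------

def read_alignment(
    path: str | Path,
    locus_name: str | None = None,
    coding: bool = False,
    genetic_code_id: str = "none",
    frame_offset: int = 0,
) -> Alignment:
    """Read a FASTA alignment, validating record lengths.

    Bases are normalised to upper case.  Ragged records and empty files are
    hard errors naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(
        locus_name=locus_name or path.stem,
        sample_ids=ids,
        sequences=seqs,
        coding=coding,
        genetic_code_id=genetic_code_id,
        frame_offset=frame_offset,
    )


def write_alignment(aln: Alignment, path: str | Path, wrap: int = 80) -> None:
    """Write FASTA wrapped at `wrap` columns."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.sample_ids, aln.sequences)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, location, country[, lineage]).

    Validates that every location code maps to exactly one country.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "location", "country"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    per_loc = meta.groupby("location")["country"].nunique()
    bad = per_loc[per_loc > 1]
    if len(bad):
        raise ValueError(
            f"locations mapping to multiple countries: {list(bad.index)}"
        )
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def partition_from_metadata(meta: pd.DataFrame, by: str = "lineage") -> LineagePartition:
    """Build a LineagePartition from a metadata table column."""
    if by not in meta.columns:
        raise ValueError(f"metadata has no '{by}' column")
    col = meta[by]
    if col.isna().any():
        bad = meta.loc[col.isna(), "sample_id"].tolist()
        raise ValueError(f"samples without '{by}' assignment: {bad}")
    return LineagePartition(
        dict(zip(meta["sample_id"], col.astype(str))), grouping_kind=by
    )


def check_metadata_covers(aln: Alignment, meta: pd.DataFrame) -> None:
    """Every aligned sample must have a metadata row."""
    missing = set(aln.sample_ids) - set(meta["sample_id"])
    if missing:
        raise ValueError(f"aligned samples without metadata: {sorted(missing)}")


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def _codon_map(code_id: str) -> dict[str, str]:
    table_id = GENETIC_CODES[code_id]
    table = CodonTable.unambiguous_dna_by_id[table_id]
    fwd = dict(table.forward_table)
    for stop in table.stop_codons:
        fwd[stop] = "*"
    return fwd


def translate(aln: Alignment) -> Alignment:
    """Translate a coding nucleotide alignment to amino acids.

    Codons containing a gap or any ambiguity character translate to ``X``;
    a trailing partial codon is dropped.
    """
    if not aln.coding:
        raise AlignmentError(f"locus '{aln.locus_name}' is not coding")
    fwd = _codon_map(aln.genetic_code_id)
    n_codons = (aln.length - aln.frame_offset) // 3
    out_seqs: list[str] = []
    for seq in aln.sequences:
        aa = []
        for c in range(n_codons):
            codon = seq[aln.frame_offset + 3 * c: aln.frame_offset + 3 * c + 3]
            aa.append(fwd.get(codon, "X"))
        out_seqs.append("".join(aa))
    return Alignment(
        locus_name=f"{aln.locus_name}_aa",
        sample_ids=list(aln.sample_ids),
        sequences=out_seqs,
        coding=False,
        genetic_code_id="none",
        is_protein=True,
    )


# ---------------------------------------------------------------------------
# Haplotype collapsing
# ---------------------------------------------------------------------------

def collapse_haplotypes(aln: Alignment) -> HaplotypeTable:
    """Group samples into haplotypes by exact sequence identity.

    Gaps and ambiguity codes are compared literally.  Haplotype ids are
    assigned in order of first occurrence (``H1``, ``H2``, ...).
    """
    level = "amino_acid" if aln.is_protein else "nucleotide"
    table = HaplotypeTable(level=level)
    seq_to_h: dict[str, str] = {}
    for sid, seq in zip(aln.sample_ids, aln.sequences):
        hid = seq_to_h.get(seq)
        if hid is None:
            hid = f"H{len(seq_to_h) + 1}"
            seq_to_h[seq] = hid
            table.haplotype_ids.append(hid)
            table.members[hid] = []
            table.representative[hid] = seq
        table.members[hid].append(sid)
    return table


def haplotype_alignment(aln: Alignment, table: HaplotypeTable) -> Alignment:
    """One representative sequence per haplotype, labelled by haplotype id."""
    return replace(
        aln,
        sample_ids=list(table.haplotype_ids),
        sequences=[table.representative[h] for h in table.haplotype_ids],
    )


# ---------------------------------------------------------------------------
# Lineage-specific substitutions
# ---------------------------------------------------------------------------

def _consensus(states: Sequence[str]) -> str:
    """Majority state; ties broken alphabetically."""
    counts: dict[str, int] = {}
    for s in states:
        counts[s] = counts.get(s, 0) + 1
    best = max(counts.values())
    return min(s for s, c in counts.items() if c == best)


def lineage_specific_substitutions(
    aln: Alignment, part: LineagePartition
) -> pd.DataFrame:
    """Screen every column for lineage-diagnostic states.

    Column ``c`` is diagnostic for lineage ``l`` iff all members of ``l``
    share one state at ``c`` and that state occurs in no other lineage.
    For coding nucleotide alignments each diagnostic column is classified
    synonymous / non-synonymous by translating the focal-lineage codon
    against the background-consensus codon (majority state at the other two
    codon positions across non-focal lineages, ties alphabetical).

    Columns are reported 1-based.
    """
    groups = part.groups()
    if len(groups) < 2:
        raise ValueError("partition must cover at least 2 lineages")
    for g, mem in groups.items():
        for s in mem:
            if s not in aln.sample_ids:
                raise ValueError(f"sample '{s}' of group '{g}' not in alignment")
    idx = {s: i for i, s in enumerate(aln.sample_ids)}
    level = "amino_acid" if aln.is_protein else "nucleotide"
    classify = aln.coding and not aln.is_protein
    fwd = _codon_map(aln.genetic_code_id) if classify else None

    rows = []
    for c in range(aln.length):
        col = [seq[c] for seq in aln.sequences]
        for lineage in sorted(groups):
            mem_states = {col[idx[s]] for s in groups[lineage]}
            if len(mem_states) != 1:
                continue
            state = next(iter(mem_states))
            other = [
                col[idx[s]]
                for g, mem in groups.items() if g != lineage
                for s in mem
            ]
            if state in other:
                continue
            background = sorted(set(other))
            synonymy = "not_applicable"
            if classify:
                synonymy = _synonymy(
                    aln, groups, idx, lineage, c, state, other, fwd
                )
            rows.append({
                "alignment_column": c + 1,
                "level": level,
                "lineage": lineage,
                "diagnostic_state": state,
                "background_states": "/".join(background),
                "synonymy": synonymy,
            })
    return pd.DataFrame(
        rows,
        columns=["alignment_column", "level", "lineage", "diagnostic_state",
                 "background_states", "synonymy"],
    )


def _synonymy(aln, groups, idx, lineage, c, state, other_states, fwd):
    pos_in_codon = (c - aln.frame_offset) % 3
    start = c - pos_in_codon
    if start < aln.frame_offset or start + 3 > aln.length:
        return "not_applicable"  # partial codon at either alignment edge
    focal_rows = [idx[s] for s in groups[lineage]]
    other_rows = [idx[s] for g, mem in groups.items() if g != lineage for s in mem]

    def codon(rows, forced=None):
        chars = []
        for k in range(3):
            states = [aln.sequences[r][start + k] for r in rows]
            chars.append(_consensus(states))
        if forced is not None:
            chars[pos_in_codon] = forced
        return "".join(chars)

    # background context: consensus of non-focal lineages at the flanking
    # codon positions; focal codon carries the diagnostic state in the same
    # context so that only the focal column differs
    context = codon(other_rows)
    focal_codon = context[:pos_in_codon] + state + context[pos_in_codon + 1:]
    background_codon = context[:pos_in_codon] + _consensus(other_states) + \
        context[pos_in_codon + 1:]
    aa_focal = fwd.get(focal_codon, "X")
    aa_back = fwd.get(background_codon, "X")
    if "X" in (aa_focal, aa_back):
        return "not_applicable"
    return "synonymous" if aa_focal == aa_back else "non_synonymous"


# ---------------------------------------------------------------------------
# Codon-position masking
# ---------------------------------------------------------------------------

def mask_codon_position(aln: Alignment, position: int) -> Alignment:
    """Remove every site at the stated codon position (1, 2 or 3).

    Codon positions are assigned cyclically from ``frame_offset``; leading
    bases before the frame and trailing partial-codon bases keep their
    cyclic position so that masking positions 1, 2 and 3 in turn removes
    disjoint site sets whose union is every site.  The returned alignment
    is no longer translatable and is flagged non-coding.
    """
    if not aln.coding:
        raise AlignmentError(f"locus '{aln.locus_name}' is not coding")
    if position not in (1, 2, 3):
        raise ValueError("codon position must be 1, 2 or 3")
    keep = [
        i for i in range(aln.length)
        if ((i - aln.frame_offset) % 3) + 1 != position
    ]
    out_seqs = ["".join(seq[i] for i in keep) for seq in aln.sequences]
    return Alignment(
        locus_name=f"{aln.locus_name}_mask{position}",
        sample_ids=list(aln.sample_ids),
        sequences=out_seqs,
        coding=False,
        genetic_code_id="none",
        is_protein=aln.is_protein,
    )
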