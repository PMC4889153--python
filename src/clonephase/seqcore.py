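"""Sequence I/O, pairwise global alignment, translation, and coordinate utilities.

Conventions used throughout the package:

* coordinates are 1-based and inclusive, relative to the ungapped CDS;
* nucleotide site ``s`` belongs to amino-acid position ``ceil(s/3)``;
* alignments use match +1 / mismatch -1 with affine gaps (a gap of length L
  costs ``gap_open + L * gap_extend``, default -4 - L) and the ambiguity
  symbols N (nucleotide) / X (amino acid) score 0 against everything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import Align, SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from clonephase.errors import ClonephaseError, FormatError

GAP = "-"
NT_CHARS = set("ACGTN")
AA_CHARS = set("ACDEFGHIKLMNPQRSTVWY*X")

_CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = tuple(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(_CODON_TABLE))


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence; ``alphabet`` is ``"nt"`` or ``"aa"``.

    Gap characters are legal only in aligned contexts; validation accepts them
    and callers that require ungapped input use :meth:`ungapped`.
    """

    id: str
    residues: str
    alphabet: Literal["nt", "aa"] = "nt"

    def __post_init__(self) -> None:
        allowed = (NT_CHARS if self.alphabet == "nt" else AA_CHARS) | {GAP}
        bad = set(self.residues.upper()) - allowed
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal {self.alphabet} characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> "SequenceRecord":
        return SequenceRecord(self.id, self.residues.replace(GAP, ""), self.alphabet)


@dataclass(frozen=True)
class DomainInterval:
    name: str
    aa_start: int  # 1-based inclusive
    aa_end: int


@dataclass
class DomainMap:
    """Named, ordered, non-overlapping amino-acid intervals for one locus."""

    locus: str
    intervals: list[DomainInterval]

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda d: d.aa_start)
        names = [d.name for d in self.intervals]
        if len(set(names)) != len(names):
            raise ClonephaseError(f"duplicate domain names in map for {self.locus}")
        prev_end = 0
        for d in self.intervals:
            if d.aa_start < 1 or d.aa_end < d.aa_start:
                raise ClonephaseError(f"bad interval {d}")
            if d.aa_start <= prev_end:
                raise ClonephaseError(f"overlapping domain intervals at {d.name}")
            prev_end = d.aa_end

    def domain_of(self, aa_pos: int) -> str:
        for d in self.intervals:
            if d.aa_start <= aa_pos <= d.aa_end:
                return d.name
        return "unmapped"


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring; a gap of length L costs ``gap_open + L*gap_extend``."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0

    def pair_score(self, a: str, b: str) -> float:
        if a in ("N", "X") or b in ("N", "X"):
            return 0.0
        return self.match if a == b else self.mismatch

    def gap_cost(self, length: int) -> float:
        return self.gap_open + length * self.gap_extend if length else 0.0


@dataclass
class PairwiseAlignment:
    a: SequenceRecord  # gapped
    b: SequenceRecord  # gapped
    score: float

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ClonephaseError("aligned sequences must have equal length")

    def columns(self) -> Iterable[tuple[str, str]]:
        return zip(self.a.residues, self.b.residues)


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path, alphabet: Literal["nt", "aa"] = "nt") -> list[SequenceRecord]:
    """Read a FASTA file, validating IDs, alphabet and non-emptiness."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for record {rec.id!r} in {path}")
        records.append(SequenceRecord(rec.id, seq, alphabet))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    bio = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Global alignment


def _substitution_matrix(alphabet: str, scoring: Scoring):
    import numpy as np
    from Bio.Align.substitution_matrices import Array

    letters = "ACGTN" if alphabet == "nt" else "ACDEFGHIKLMNPQRSTVWYX*"
    m = Array(letters, dims=2, data=np.zeros((len(letters), len(letters))))
    for x in letters:
        for y in letters:
            m[x, y] = scoring.pair_score(x, y)
    return m


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    scoring: Scoring | None = None,
    codon_aware: bool = False,
) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps.

    With ``codon_aware=True``, a post-pass shifts gap runs whose length is a
    multiple of 3 onto the nearest codon boundary whenever the shift leaves the
    alignment score unchanged — keeping codon-multiple indels in frame.
    """
    if scoring is None:
        scoring = Scoring()
    if a.alphabet != b.alphabet:
        raise ClonephaseError("cannot align sequences of different alphabets")
    if not a.residues or not b.residues:
        raise ClonephaseError("cannot align empty sequences")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _substitution_matrix(a.alphabet, scoring)
    # Biopython scores the first gap position with open_gap_score, so our
    # convention (open + L*extend) maps to open+extend / extend.
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    aln = aligner.align(a.residues.upper(), b.residues.upper())[0]
    ga, gb = str(aln[0]), str(aln[1])
    if codon_aware:
        ga, gb = _shift_codon_gaps(ga, gb, scoring)
    return PairwiseAlignment(
        SequenceRecord(a.id, ga, a.alphabet),
        SequenceRecord(b.id, gb, b.alphabet),
        float(aln.score),
    )


def alignment_score(ga: str, gb: str, scoring: Scoring) -> float:
    """Score a pair of gapped sequences under this package's gap convention."""
    score = 0.0
    run_a = run_b = 0
    for x, y in zip(ga, gb):
        if x == GAP and y == GAP:
            raise ClonephaseError("double-gap column")
        if x == GAP:
            run_a += 1
            if run_b:
                score += scoring.gap_cost(run_b)
                run_b = 0
        elif y == GAP:
            run_b += 1
            if run_a:
                score += scoring.gap_cost(run_a)
                run_a = 0
        else:
            score += scoring.gap_cost(run_a) + scoring.gap_cost(run_b)
            run_a = run_b = 0
            score += scoring.pair_score(x, y)
    score += scoring.gap_cost(run_a) + scoring.gap_cost(run_b)
    return score


def _gap_runs(s: str) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i < len(s):
        if s[i] == GAP:
            j = i
            while j < len(s) and s[j] == GAP:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _shift_codon_gaps(ga: str, gb: str, scoring: Scoring) -> tuple[str, str]:
    """Move codon-multiple gap runs to codon boundaries when score-neutral.

    The boundary is defined on the gapped sequence's own reading frame: the
    number of its residues preceding the gap must be a multiple of 3.
    """
    base = alignment_score(ga, gb, scoring)
    for which in (0, 1):
        gapped, other = (ga, gb) if which == 0 else (gb, ga)
        changed = True
        while changed:
            changed = False
            for i, j in _gap_runs(gapped):
                length = j - i
                if length % 3 != 0:
                    continue
                ungapped_before = len(gapped[:i].replace(GAP, ""))
                r = ungapped_before % 3
                if r == 0:
                    continue
                for delta in (-r, 3 - r, -r - 3, 6 - r):
                    cand = _try_shift(gapped, i, j, delta)
                    if cand is None:
                        continue
                    try:
                        cand_score = alignment_score(cand, other, scoring)
                    except ClonephaseError:  # shift collided with a gap in the partner
                        continue
                    if cand_score == base:
                        gapped = cand
                        changed = True
                        break
                if changed:
                    break
        if which == 0:
            ga = gapped
        else:
            gb = gapped
    return ga, gb


def _try_shift(gapped: str, i: int, j: int, delta: int) -> str | None:
    """Shift gap run [i, j) by delta positions; None if it would collide."""
    chars = list(gapped)
    length = j - i
    ni = i + delta
    if ni < 0 or ni + length > len(chars):
        return None
    if delta < 0:
        moved = chars[ni:i]
    else:
        moved = chars[j : j + delta]
    if GAP in moved:
        return None
    if delta < 0:
        new = chars[:ni] + [GAP] * length + moved + chars[j:]
    else:
        new = chars[:i] + moved + [GAP] * length + chars[j + delta :]
    return "".join(new)


# ---------------------------------------------------------------------------
# Translation & coordinates


def translate(cds: SequenceRecord) -> SequenceRecord:
    """Translate a CDS (standard code); an all-gap codon yields a gap residue.

    Internal stop codons are kept as ``*`` in the output rather than
    truncating; use :func:`internal_stop_positions` to flag them.
    """
    seq = cds.residues.upper()
    if len(seq.replace(GAP, "")) % 3 != 0:
        raise ClonephaseError(
            f"{cds.id}: ungapped CDS length {len(seq.replace(GAP, ''))} not a multiple of 3"
        )
    if len(seq) % 3 != 0:
        raise ClonephaseError(f"{cds.id}: gapped length not a multiple of 3")
    out = []
    for k in range(0, len(seq), 3):
        codon = seq[k : k + 3]
        if codon == "---":
            out.append(GAP)
        elif GAP in codon:
            raise ClonephaseError(f"{cds.id}: partial gap codon {codon!r} at nt {k + 1}")
        elif "N" in codon:
            out.append("X")
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append(_CODON_TABLE[codon])
    return SequenceRecord(cds.id, "".join(out), "aa")


def internal_stop_positions(aa: SequenceRecord) -> list[int]:
    """1-based aa positions of stop codons before the final residue."""
    return [i + 1 for i, r in enumerate(aa.residues[:-1]) if r == "*"]


def nt_site_to_aa_pos(site: int) -> int:
    """Map a 1-based CDS nucleotide position to its 1-based codon number."""
    if site < 1:
        raise ClonephaseError(f"nucleotide site must be >= 1, got {site}")
    return math.ceil(site / 3)


def domain_identity(
    seq: SequenceRecord, ref: SequenceRecord, domain_map: DomainMap
) -> dict[str, float]:
    """Percent amino-acid identity per domain, relative to the reference.

    ``seq`` and ``ref`` must already be aligned (equal gapped length); domain
    coordinates refer to the reference's ungapped positions. Identity counts
    only columns at which the reference is non-gap, and is rounded to one
    decimal.
    """
    if len(seq) != len(ref):
        raise ClonephaseError("domain_identity requires aligned (equal-length) input")
    ref_len = len(ref.residues.replace(GAP, ""))
    out: dict[str, float] = {}
    for d in domain_map.intervals:
        if d.aa_end > ref_len:
            raise ClonephaseError(
                f"domain {d.name} extends past reference length {ref_len}"
            )
        match = total = 0
        pos = 0
        for s, r in zip(seq.residues, ref.residues):
            if r == GAP:
                continue
            pos += 1
            if d.aa_start <= pos <= d.aa_end:
                total += 1
                if s == r:
                    match += 1
        out[d.name] = round(100.0 * match / total, 1)
    return out


def leftmost_codon_deletion(ref_codons: Sequence[str], p1: int, n_codons: int) -> int:
    """Canonical (leftmost) start codon for a deletion of ``n_codons`` codons.

    In repetitive context a deletion's placement is ambiguous — removing codons
    [p1, p1+n-1] yields the same sequence as removing [p1-1, p1+n-2] whenever
    codon p1-1 equals codon p1+n-1. Both the simulator's ground truth and the
    detector normalise to the leftmost equivalent placement so representations
    are comparable. Positions are 1-based.
    """
    while p1 > 1 and ref_codons[p1 - 2] == ref_codons[p1 + n_codons - 2]:
        p1 -= 1
    return p1


def leftmost_codon_insertion(
    ref_codons: Sequence[str], after: int, block: Sequence[str]
) -> tuple[int, list[str]]:
    """Canonical (leftmost) placement for a codon block inserted after codon
    ``after`` (0 = before the first codon); returns the shifted anchor and the
    rotated block. Inserting block B after codon k equals inserting
    [codon_k] + B[:-1] after k-1 whenever B[-1] == codon_k.
    """
    block = list(block)
    while after >= 1 and block and block[-1] == ref_codons[after - 1]:
        block = [ref_codons[after - 1]] + block[:-1]
        after -= 1
    return after, block


def read_domain_map(path: str | Path) -> dict[str, DomainMap]:
    """Read a TSV with columns locus, name, aa_start, aa_end."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"locus", "name", "aa_start", "aa_end"}
    if not required.issubset(df.columns):
        raise FormatError(f"domain map must have columns {sorted(required)}")
    maps = {}
    for locus, grp in df.groupby("locus"):
        maps[str(locus)] = DomainMap(
            str(locus),
            [
                DomainInterval(str(row["name"]), int(row["aa_start"]), int(row["aa_end"]))
                for _, row in grp.iterrows()
            ],
        )
    return maps


def write_domain_map(maps: dict[str, DomainMap], path: str | Path) -> None:
    import pandas as pd

    rows = [
        {"locus": m.locus, "name": d.name, "aa_start": d.aa_start, "aa_end": d.aa_end}
        for m in maps.values()
        for d in m.intervals
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
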