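"""Polymorphism detection and classification over the four-lineage quartet.

The quartet orders the lineage sequences as (Pm, Pf1, Pf2, Pl): the maternal
ancestor species, the hybrid's maternally and paternally derived alleles, and
the paternal ancestor species. After canonical ordering Pf1 is the allele of
Pm origin and Pf2 the allele of Pl origin, so a difference that predates the
hybridization ("ancestral") shows the signature Pm=Pf1 ≠ Pf2=Pl, while a
mutation arising afterwards is private to exactly one of the four sequences
("derived in" that lineage). Loci at which the hybrid expresses a single
allele are handled as a trio (Pm, Pf, Pl) with the corresponding rules.

Substitutions are named against a reference lineage (default Pl) in a concise
protein-level code — ``V87A``, ``G173_V178del``, ``247,AV,.`` — and summarized
per protein domain. The module also profiles conservation of focal positions
in homolog alignments and exports ancestral-polarity sites as allele-specific
expression (ASE) SNP markers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from clonephase.errors import ClonephaseError
from clonephase.phasing import AlleleCall, _project_to_anchor
from clonephase.seqcore import (
    GAP,
    DomainMap,
    SequenceRecord,
    _CODON_TABLE,
    leftmost_codon_deletion,
    leftmost_codon_insertion,
    nt_site_to_aa_pos,
)

QUARTET_TAGS = ("Pm", "Pf1", "Pf2", "Pl")
TRIO_TAGS = ("Pm", "Pf", "Pl")


@dataclass
class LineageQuartet:
    """Mutually aligned lineage CDS for one locus (quartet or trio)."""

    locus: str
    seqs: dict[str, SequenceRecord]

    def __post_init__(self) -> None:
        tags = tuple(self.seqs)
        if tags not in (QUARTET_TAGS, TRIO_TAGS):
            raise ClonephaseError(
                f"lineage tags must be {QUARTET_TAGS} or {TRIO_TAGS}, got {tags}"
            )
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) != 1:
            raise ClonephaseError("quartet sequences must be aligned (equal length)")

    @property
    def is_trio(self) -> bool:
        return len(self.seqs) == 3

    @property
    def tags(self) -> tuple[str, ...]:
        return tuple(self.seqs)

    def width(self) -> int:
        return len(next(iter(self.seqs.values())))


def build_quartet(locus: str, seqs: dict[str, SequenceRecord]) -> LineageQuartet:
    """Star-align lineage sequences to the longest and wrap as a quartet/trio."""
    order = QUARTET_TAGS if len(seqs) == 4 else TRIO_TAGS
    if set(seqs) != set(order):
        raise ClonephaseError(f"expected lineage tags {order}, got {sorted(seqs)}")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) == 1:
        aligned = {t: seqs[t].residues for t in order}
    else:
        aligned = _project_to_anchor(dict(seqs))
    return LineageQuartet(
        locus,
        {t: SequenceRecord(f"{locus}_{t}", aligned[t], "nt") for t in order},
    )


def quartet_from_phasing(
    locus: str,
    call: AlleleCall,
    origins: dict[str, str],
    parent_refs: dict[str, SequenceRecord],
) -> LineageQuartet:
    """Assemble the quartet from a phased hybrid call and the parental references.

    Hybrid alleles are canonically ordered by origin (Pf1 = Pm origin,
    Pf2 = Pl origin); a single-haplotype call yields the trio with the hybrid
    allele in the middle.
    """
    haps = call.ungapped_haplotypes()
    if len(haps) == 1:
        seqs = {"Pm": parent_refs["Pm"], "Pf": haps[0], "Pl": parent_refs["Pl"]}
        return build_quartet(locus, seqs)
    by_origin = {origins[h.id]: h for h in haps}
    if set(by_origin) != {"Pm", "Pl"}:
        raise ClonephaseError(
            f"cannot canonically order hybrid alleles with origins {origins}"
        )
    seqs = {
        "Pm": parent_refs["Pm"],
        "Pf1": by_origin["Pm"],
        "Pf2": by_origin["Pl"],
        "Pl": parent_refs["Pl"],
    }
    return build_quartet(locus, seqs)


@dataclass
class PolymorphicSite:
    """One variant site (or contiguous indel event) among the lineages."""

    nt_site: int  # 1-based position in the naming reference (first nt for indels)
    aa_pos: int
    kind: str  # substitution | insertion | deletion
    pattern: tuple[str, ...]  # residue (or residue-run) per lineage, in tag order
    polarity: str = "unclassified"
    coding_effect: str = ""  # synonymous | nonsynonymous | indel | frameshift
    aa_pattern: tuple[str, ...] = ()
    code: str = ""
    domain: str = "unmapped"
    length_nt: int = 1
    columns: tuple[int, ...] = ()  # 0-based alignment columns (internal)


# ---------------------------------------------------------------------------
# Detection


def _ungapped_pos_maps(quartet: LineageQuartet) -> dict[str, list[int]]:
    """Per lineage: alignment column -> 1-based ungapped position (0 if gap,
    carrying the position of the last preceding residue for gap columns)."""
    maps = {}
    for tag, rec in quartet.seqs.items():
        pos = 0
        col_map = []
        for ch in rec.residues:
            if ch != GAP:
                pos += 1
            col_map.append(pos)
        maps[tag] = col_map
    return maps


def detect_polymorphisms(
    quartet: LineageQuartet,
    domain_map: DomainMap | None = None,
    reference: str = "Pl",
) -> list[PolymorphicSite]:
    """All sites at which the lineage sequences differ.

    Contiguous alignment columns sharing one gap pattern are emitted as a
    single indel event; differing non-gap columns are emitted per reference
    codon (several changed nucleotides within one codon collapse into one
    amino-acid-level record anchored at the first changed position). Sites are
    classified for polarity and coding effect and given a substitution code.
    """
    tags = quartet.tags
    seqs = [quartet.seqs[t].residues for t in tags]
    width = quartet.width()
    pos_maps = _ungapped_pos_maps(quartet)
    ref_map = pos_maps[reference]
    ref_seq = quartet.seqs[reference].residues

    sites: list[PolymorphicSite] = []

    # --- indel events: runs of columns with a constant, non-trivial gap pattern
    col = 0
    sub_columns: list[int] = []
    while col < width:
        gap_pat = tuple(s[col] == GAP for s in seqs)
        if any(gap_pat):
            start = col
            while col < width and tuple(s[col] == GAP for s in seqs) == gap_pat:
                col += 1
            sites.append(
                _make_indel_site(quartet, tags, start, col, gap_pat, ref_map, ref_seq, pos_maps, reference)
            )
        else:
            residues = {s[col] for s in seqs}
            if len(residues) > 1:
                sub_columns.append(col)
            col += 1

    # --- substitutions, grouped by reference codon
    by_codon: dict[int, list[int]] = {}
    for c in sub_columns:
        ref_pos = ref_map[c]
        by_codon.setdefault(nt_site_to_aa_pos(ref_pos), []).append(c)
    for aa_pos in sorted(by_codon):
        cols = tuple(sorted(by_codon[aa_pos]))
        pattern = tuple("".join(s[c] for c in cols) for s in seqs)
        site = PolymorphicSite(
            nt_site=ref_map[cols[0]],
            aa_pos=aa_pos,
            kind="substitution",
            pattern=pattern,
            columns=cols,
        )
        site.polarity = classify_polarity(pattern)
        classify_coding_effect(site, quartet, reference)
        site.code = substitution_code(site)
        if domain_map is not None:
            site.domain = domain_map.domain_of(site.aa_pos)
        sites.append(site)

    if domain_map is not None:
        for s in sites:
            s.domain = domain_map.domain_of(s.aa_pos)
    return sorted(sites, key=lambda s: (s.nt_site, s.kind))


def _make_indel_site(
    quartet, tags, start, stop, gap_pat, ref_map, ref_seq, pos_maps, reference
) -> PolymorphicSite:
    length = stop - start
    gap_tuple = tuple(GAP if g else "+" for g in gap_pat)
    polarity = classify_polarity(gap_tuple)
    ref_idx = tags.index(reference)
    ref_gapped = gap_pat[ref_idx]
    carriers = [t for t, g in zip(tags, gap_pat) if g]  # lineages lacking residues
    donor = next(t for t, g in zip(tags, gap_pat) if not g)
    donor_rec = quartet.seqs[donor]
    donor_run = donor_rec.residues[start:stop]

    site = PolymorphicSite(
        nt_site=(ref_map[start] if not ref_gapped else ref_map[start]),
        aa_pos=0,
        kind="insertion" if ref_gapped else "deletion",
        pattern=gap_tuple,
        polarity=polarity,
        coding_effect="indel" if length % 3 == 0 else "frameshift",
        length_nt=length,
        columns=tuple(range(start, stop)),
    )

    if length % 3 != 0:
        site.aa_pos = nt_site_to_aa_pos(max(site.nt_site, 1))
        return site

    n_codons = length // 3
    ref_ungapped = ref_seq.replace(GAP, "")
    ref_codons = [ref_ungapped[k : k + 3] for k in range(0, len(ref_ungapped), 3)]
    if not ref_gapped:
        # deletion relative to the reference: name the deleted residues at the
        # canonical leftmost-equivalent placement
        p1 = nt_site_to_aa_pos(ref_map[start])
        p1 = leftmost_codon_deletion(ref_codons, p1, n_codons)
        p2 = p1 + n_codons - 1
        a1 = _CODON_TABLE.get(ref_codons[p1 - 1], "?")
        a2 = _CODON_TABLE.get(ref_codons[p2 - 1], "?")
        site.code = f"{a1}{p1}del" if n_codons == 1 else f"{a1}{p1}_{a2}{p2}del"
        site.nt_site = 3 * (p1 - 1) + 1
        site.aa_pos = p1
    else:
        # insertion relative to the reference, left-shifted to the canonical
        # equivalent placement
        before = ref_map[start]  # last reference residue preceding the run
        before_aa = nt_site_to_aa_pos(before) if before else 0
        block = [donor_run[k : k + 3] for k in range(0, length, 3)]
        before_aa, block = leftmost_codon_insertion(ref_codons, before_aa, block)
        ins_aa = "".join(_CODON_TABLE.get(c, "?") for c in block)
        site.code = f"{before_aa},{ins_aa},."
        site.nt_site = 3 * before_aa + 1
        site.aa_pos = before_aa + 1
    return site


# ---------------------------------------------------------------------------
# Classification


def classify_polarity(pattern: Sequence[str]) -> str:
    """Polarity of a residue pattern in lineage order.

    Quartet (Pm, Pf1, Pf2, Pl): ancestral iff Pm=Pf1 ≠ Pf2=Pl; derived in a
    species iff that species alone differs; derived in the hybrid iff exactly
    one hybrid allele differs from its origin parent while the other three
    agree. Trio (Pm, Pf, Pl): the single deviant lineage is the derived one.
    """
    p = tuple(pattern)
    if len(p) == 4:
        pm, pf1, pf2, pl = p
        if pm == pf1 and pf2 == pl and pm != pf2:
            return "ancestral"
        if pf1 == pf2 == pl and pm != pf1:
            return "derived_in_Pm"
        if pm == pf1 == pf2 and pl != pm:
            return "derived_in_Pl"
        if pm == pf2 == pl and pf1 != pm:
            return "derived_in_Pf"
        if pm == pf1 == pl and pf2 != pm:
            return "derived_in_Pf"
        return "unclassified"
    if len(p) == 3:
        pm, pf, pl = p
        if pm == pf and pf != pl:
            return "derived_in_Pl"
        if pf == pl and pm != pf:
            return "derived_in_Pm"
        if pm == pl and pf != pm:
            return "derived_in_Pf"
        return "unclassified"
    raise ClonephaseError(f"pattern must have 3 or 4 lineages, got {len(p)}")


def classify_coding_effect(
    site: PolymorphicSite, quartet: LineageQuartet, reference: str = "Pl"
) -> str:
    """Synonymous iff the affected codon translates identically in all lineages."""
    if site.kind in ("insertion", "deletion"):
        site.coding_effect = "indel" if site.length_nt % 3 == 0 else "frameshift"
        return site.coding_effect
    pos_maps = _ungapped_pos_maps(quartet)
    col = site.columns[0]
    aas = []
    for tag in quartet.tags:
        rec = quartet.seqs[tag]
        if rec.residues[col] == GAP:
            aas.append(GAP)
            continue
        pos = pos_maps[tag][col]
        aa_idx = nt_site_to_aa_pos(pos)
        ungapped = rec.residues.replace(GAP, "")
        codon = ungapped[3 * (aa_idx - 1) : 3 * aa_idx]
        aas.append(_CODON_TABLE.get(codon, "*"))
    site.aa_pattern = tuple(aas)
    site.coding_effect = (
        "synonymous" if len(set(aas)) == 1 else "nonsynonymous"
    )
    return site.coding_effect


def substitution_code(site: PolymorphicSite, reference_index: int = -1) -> str:
    """Protein-level code for a substitution site, named against the reference
    lineage (by default the last in the pattern, i.e. Pl).

    Non-synonymous: ``<refAA><aaPos><altAA>`` (V87A). Synonymous changes get a
    nucleotide-level code ``<site><refNT>>altNT>``. Indel codes are assigned at
    detection time; calling this on a frameshift raises.
    """
    if site.coding_effect == "frameshift":
        raise ClonephaseError("no substitution code for frameshift events")
    if site.kind != "substitution":
        return site.code
    ref_nt = site.pattern[reference_index]
    alt_nts = sorted({p for p in site.pattern if p != ref_nt})
    if not alt_nts:
        return ""
    if site.coding_effect == "synonymous":
        return f"{site.nt_site}{ref_nt}>{alt_nts[0]}"
    ref_aa = site.aa_pattern[reference_index]
    alt_aa = sorted({a for a in site.aa_pattern if a != ref_aa})[0]
    return f"{ref_aa}{site.aa_pos}{alt_aa}"


# ---------------------------------------------------------------------------
# Summaries & exports


def sites_to_frame(sites: Sequence[PolymorphicSite], locus: str = "") -> pd.DataFrame:
    rows = [
        {
            "locus": locus,
            "nt_site": s.nt_site,
            "aa_pos": s.aa_pos,
            "kind": s.kind if s.kind == "substitution" else s.kind,
            "pattern": "-".join(s.pattern) if s.kind == "substitution" else "",
            "pattern_aa": "-".join(s.aa_pattern) if s.aa_pattern else "",
            "polarity": s.polarity,
            "coding_effect": s.coding_effect,
            "domain": s.domain,
            "code": s.code,
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "locus",
            "nt_site",
            "aa_pos",
            "kind",
            "pattern",
            "pattern_aa",
            "polarity",
            "coding_effect",
            "domain",
            "code",
        ],
    )


def summarize_by_domain(
    sites: Sequence[PolymorphicSite], domain_map: DomainMap
) -> pd.DataFrame:
    """Cross-tabulation of site counts: domain x polarity x coding effect.

    Every domain in the map appears (plus ``unmapped``), with zero counts where
    no site falls in it.
    """
    domains = [d.name for d in domain_map.intervals] + ["unmapped"]
    polarities = sorted({s.polarity for s in sites}) or ["ancestral"]
    effects = sorted({s.coding_effect for s in sites}) or ["nonsynonymous"]
    counts = {
        (d, p, e): 0 for d in domains for p in polarities for e in effects
    }
    for s in sites:
        d = s.domain if s.domain in domains else "unmapped"
        counts[(d, s.polarity, s.coding_effect)] += 1
    rows = [
        {"domain": d, "polarity": p, "coding_effect": e, "count": n}
        for (d, p, e), n in counts.items()
    ]
    return pd.DataFrame(rows)


def domain_totals(summary: pd.DataFrame, polarity: str | None = None) -> dict[str, int]:
    df = summary
    if polarity is not None:
        df = df[df.polarity == polarity]
    return df.groupby("domain")["count"].sum().to_dict()


def conservation_profile(
    alignment: Sequence[SequenceRecord],
    focal_positions: Sequence[int],
    focal_residues: dict[int, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per focal column: variability, major residue and frequency, and the
    frequencies of the residues observed in the study alleles.

    Positions are 1-based alignment columns; frequencies are percentages over
    non-gap rows.
    """
    if not alignment:
        raise ClonephaseError("empty alignment")
    rows = []
    for pos in focal_positions:
        col = [rec.residues[pos - 1] for rec in alignment]
        col = [c for c in col if c != GAP]
        if not col:
            raise ClonephaseError(f"column {pos} is all-gap")
        counts = pd.Series(col).value_counts()
        major = counts.index[0]
        row = {
            "position": pos,
            "variability": int(counts.size),
            "major_residue": major,
            "major_frequency": round(100.0 * counts.iloc[0] / len(col), 1),
        }
        if focal_residues and pos in focal_residues:
            for r in focal_residues[pos]:
                row[f"freq_{r}"] = round(100.0 * counts.get(r, 0) / len(col), 1)
        rows.append(row)
    return pd.DataFrame(rows)


def export_ase_snps(
    sites: Sequence[PolymorphicSite], locus: str = ""
) -> pd.DataFrame:
    """Allele-distinguishing SNP markers: the ancestral-polarity substitutions.

    These are the positions at which the hybrid's two alleles differ by
    parental origin, usable to design allele-specific expression assays.
    """
    rows = []
    for s in sites:
        if s.polarity != "ancestral" or s.kind != "substitution":
            continue
        rows.append(
            {
                "locus": locus,
                "nt_site": s.nt_site,
                "pm_residue": s.pattern[0],
                "pl_residue": s.pattern[-1],
                "aa_pos": s.aa_pos,
                "coding_effect": s.coding_effect,
                "domain": s.domain,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus",
            "nt_site",
            "pm_residue",
            "pl_residue",
            "aa_pos",
            "coding_effect",
            "domain",
        ],
    )


def join_annotations(sites_df: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Left-join externally computed impact predictions on the ``code`` column.

    Protein-impact scores (e.g. PolyPhen-2 / PROVEAN output) are ingested as
    pass-through annotation, never computed here.
    """
    if "code" not in annotations.columns:
        raise ClonephaseError("annotation table must have a 'code' column")
    return sites_df.merge(annotations, on="code", how="left")
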