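"""Allele reconstruction from cloned Sanger sequences.

A heterozygous individual amplified by PCR and sequenced clone-by-clone yields
inherently phased reads: each clone derives from a single template molecule.
This module clusters clones into (at most two) haplotypes, screens for PCR
template-switch chimeras — artifactual single-crossover recombinants of the two
alleles — assigns each reconstructed haplotype to the parental species it
matches, and tests whether observing only one allele among ``n`` clones is
compatible with balanced sampling of two alleles (Pearson χ², df=1).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from clonephase.errors import ClonephaseError, PhasingError
from clonephase.seqcore import GAP, SequenceRecord, global_align

DEFAULT_MIN_SUPPORT = 2
DEFAULT_MIN_SEGMENT = 2
DEFAULT_MAX_ISOLATED_ERRORS = 1


@dataclass
class CloneSet:
    """Clone sequences for one locus and individual, aligned to a common frame.

    If clones differ in length (alleles separated by an indel), call
    :meth:`aligned` to project all clones onto the coordinates of the longest
    clone before site calling.
    """

    locus: str
    species: str
    individual: str
    clones: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.clones:
            raise ClonephaseError("clone set must contain at least one clone")

    def aligned(self) -> "CloneSet":
        lengths = {len(c) for c in self.clones}
        if len(lengths) == 1:
            return self
        anchor = max(self.clones, key=len)
        out = []
        for c in self.clones:
            if len(c) == len(anchor):
                out.append(c)
            else:
                aln = global_align(anchor, c, codon_aware=True)
                if len(aln.a) != len(anchor):
                    raise PhasingError(
                        f"clone {c.id} requires insertions relative to the longest "
                        "clone; clone set is not star-alignable"
                    )
                out.append(aln.b)
        return CloneSet(self.locus, self.species, self.individual, out)


@dataclass
class AlleleCall:
    haplotypes: list[SequenceRecord]  # 1 or 2 consensus sequences (aligned frame)
    support: list[int]  # clones backing each haplotype
    informative_sites: list[int]  # 0-based columns distinguishing the haplotypes
    excluded_clones: list[str]  # IDs removed as putative chimeras / low quality
    clone_assignment: dict[str, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.haplotypes) == 1 and self.informative_sites:
            raise ClonephaseError("single-haplotype call cannot have informative sites")

    def ungapped_haplotypes(self) -> list[SequenceRecord]:
        return [h.ungapped() for h in self.haplotypes]


@dataclass
class CloneVerdict:
    clone_id: str
    verdict: str  # clean_A | clean_B | chimeric | ambiguous
    switch_points: list[int]  # indices into the informative-site list
    mismatch_count: int


@dataclass
class ChimeraReport:
    verdicts: list[CloneVerdict]

    def chimeric_ids(self) -> list[str]:
        return [v.clone_id for v in self.verdicts if v.verdict == "chimeric"]


@dataclass
class AlleleDetectionTest:
    n_clones: int
    observed: tuple[int, int]
    chi2: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------


def call_variant_sites(
    clone_set: CloneSet, min_support: int = DEFAULT_MIN_SUPPORT
) -> list[int]:
    """0-based columns at which >=2 residues each occur in >= min_support clones.

    Residues seen in fewer than ``min_support`` clones at a column are treated
    as putative amplification/sequencing errors rather than variants.
    """
    cs = clone_set.aligned()
    n_cols = len(cs.clones[0])
    sites = []
    for col in range(n_cols):
        counts = Counter(c.residues[col] for c in cs.clones)
        supported = [r for r, n in counts.items() if n >= min_support]
        if len(supported) >= 2:
            sites.append(col)
    return sites


def _cluster_vectors(
    clones: Sequence[SequenceRecord], sites: Sequence[int]
) -> dict[tuple[str, ...], list[int]]:
    clusters: dict[tuple[str, ...], list[int]] = defaultdict(list)
    for i, c in enumerate(clones):
        vec = tuple(c.residues[s] for s in sites)
        clusters[vec].append(i)
    return dict(clusters)


def _is_mosaic_of(vec, a, b) -> bool:
    """True if every element matches the corresponding element of a or b."""
    return all(v == x or v == y for v, x, y in zip(vec, a, b))


def infer_alleles(
    clone_set: CloneSet,
    min_support: int = DEFAULT_MIN_SUPPORT,
    max_isolated_errors: int = DEFAULT_MAX_ISOLATED_ERRORS,
) -> AlleleCall:
    """Cluster clones by their residue vector over variant sites; call <=2 haplotypes.

    Clones are grouped by their exact vector over the variant sites. Clusters
    within ``max_isolated_errors`` sites of the best-supported cluster are
    merged into it (a shared sequencing error can fabricate an apparent second
    allele, so alleles closer than ``max_isolated_errors + 1`` variant sites
    are declared unresolvable rather than split). The best-supported remaining
    cluster becomes the second haplotype provided it is itself confirmed by at
    least ``min_support`` clones; leftover clones are attached
    to the nearest haplotype if they differ at no more than
    ``max_isolated_errors`` sites, and excluded otherwise (putative chimeras or
    low-quality clones — screened explicitly by :func:`detect_chimeras`). A
    third well-supported cluster whose vector is *not* explainable as a mosaic
    of the two haplotypes signals contamination or paralog co-amplification and
    raises :class:`PhasingError`.

    Consensus per cluster is the per-column majority over member clones.
    """
    cs = clone_set.aligned()
    sites = call_variant_sites(cs, min_support=min_support)
    clones = cs.clones

    if not sites:
        consensus = _column_majority(clones, range(len(clones[0])))
        hap = SequenceRecord(f"{cs.locus}_hap1", consensus, clones[0].alphabet)
        return AlleleCall(
            haplotypes=[hap],
            support=[len(clones)],
            informative_sites=[],
            excluded_clones=[],
            clone_assignment={c.id: 0 for c in clones},
        )

    clusters = _cluster_vectors(clones, sites)
    ranked = sorted(clusters.items(), key=lambda kv: (-len(kv[1]), kv[0]))

    def dist(u, v):
        return sum(1 for x, y in zip(u, v) if x != y)

    # Clusters within sequencing-error distance of the best-supported cluster
    # are the same allele (the attachment rule applied to cluster selection
    # itself): alleles closer than max_isolated_errors + 1 variant sites are
    # unresolvable by construction.
    vec_a = ranked[0][0]
    members_a = list(ranked[0][1])
    rest: list[tuple[tuple[str, ...], list[int]]] = []
    for vec, members in ranked[1:]:
        if dist(vec, vec_a) <= max_isolated_errors:
            members_a.extend(members)
        else:
            rest.append((vec, members))

    if not rest or len(rest[0][1]) < min_support:
        # single-allele locus (or homozygote): apparent variant sites are
        # shared sequencing errors; a putative second allele must itself be
        # confirmed by min_support clones, otherwise its clones are excluded
        excluded = [clones[i].id for _, members in rest for i in members]
        consensus = _column_majority(
            [clones[i] for i in members_a], range(len(clones[0]))
        )
        hap = SequenceRecord(f"{cs.locus}_hap1", consensus, clones[0].alphabet)
        assignment = {clones[i].id: 0 for i in members_a}
        assignment.update({cid: None for cid in excluded})
        return AlleleCall(
            haplotypes=[hap],
            support=[len(members_a)],
            informative_sites=[],
            excluded_clones=excluded,
            clone_assignment=assignment,
        )

    vec_b = rest[0][0]
    members_b = list(rest[0][1])
    excluded: list[str] = []
    assignment: dict[str, int | None] = {}
    for vec, members in rest[1:]:
        d_a, d_b = dist(vec, vec_a), dist(vec, vec_b)
        if min(d_a, d_b) <= max_isolated_errors:
            (members_a if d_a <= d_b else members_b).extend(members)
        elif len(members) >= min_support and not _is_mosaic_of(vec, vec_a, vec_b):
            raise PhasingError(
                "a third well-supported cluster is neither error-compatible with "
                "nor a mosaic of the two haplotypes (possible contamination or "
                "paralog co-amplification)"
            )
        else:
            excluded.extend(clones[i].id for i in members)
    for i in members_a:
        assignment[clones[i].id] = 0
    for i in members_b:
        assignment[clones[i].id] = 1
    for cid in excluded:
        assignment[cid] = None

    hap_a = _column_majority([clones[i] for i in members_a], range(len(clones[0])))
    hap_b = _column_majority([clones[i] for i in members_b], range(len(clones[0])))
    informative = [c for c in range(len(hap_a)) if hap_a[c] != hap_b[c]]
    haps = [
        SequenceRecord(f"{cs.locus}_hap1", hap_a, clones[0].alphabet),
        SequenceRecord(f"{cs.locus}_hap2", hap_b, clones[0].alphabet),
    ]
    return AlleleCall(
        haplotypes=haps,
        support=[len(members_a), len(members_b)],
        informative_sites=informative,
        excluded_clones=excluded,
        clone_assignment=assignment,
    )


def _column_majority(clones: Sequence[SequenceRecord], cols) -> str:
    out = []
    for col in cols:
        counts = Counter(c.residues[col] for c in clones)
        # deterministic tie-break: highest count, then lexicographic residue
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        out.append(best)
    return "".join(out)


def detect_chimeras(
    clone_set: CloneSet,
    call: AlleleCall,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    max_isolated_errors: int = DEFAULT_MAX_ISOLATED_ERRORS,
) -> ChimeraReport:
    """Screen each clone for the template-switch mosaic signature.

    Each clone's residue vector over the informative sites is expressed as a
    string of A/B states (``?`` where it matches neither haplotype). A clone is

    * ``clean_A``/``clean_B`` if it matches one haplotype at every informative
      site except at most ``max_isolated_errors`` isolated positions,
    * ``chimeric`` if the A/B states form >=2 contiguous segments, each
      spanning at least ``min_segment`` informative sites,
    * ``ambiguous`` otherwise.
    """
    if len(call.haplotypes) < 2:
        raise ClonephaseError("chimera screening requires a two-haplotype call")
    cs = clone_set.aligned()
    sites = call.informative_sites
    hap_a = call.haplotypes[0].residues
    hap_b = call.haplotypes[1].residues

    verdicts = []
    for clone in cs.clones:
        states = []
        for s in sites:
            r = clone.residues[s]
            if r == hap_a[s]:
                states.append("A")
            elif r == hap_b[s]:
                states.append("B")
            else:
                states.append("?")
        verdicts.append(_classify_states(clone.id, states, min_segment, max_isolated_errors))
    return ChimeraReport(verdicts)


def _runs(states: list[str]) -> list[tuple[str, int, int]]:
    """Maximal runs of identical states as (state, start, end_exclusive)."""
    runs = []
    i = 0
    while i < len(states):
        j = i
        while j < len(states) and states[j] == states[i]:
            j += 1
        runs.append((states[i], i, j))
        i = j
    return runs


def _classify_states(
    clone_id: str, states: list[str], min_segment: int, max_isolated: int
) -> CloneVerdict:
    n_a = states.count("A")
    n_b = states.count("B")
    n_q = states.count("?")
    runs = [r for r in _runs(states) if r[0] != "?"]

    # clean: all one state except <= max_isolated isolated opposite/unknown sites
    for major, minor_count in (("A", n_b + n_q), ("B", n_a + n_q)):
        if minor_count <= max_isolated:
            isolated = all(
                (r[2] - r[1]) == 1 for r in _runs(states) if r[0] != major
            )
            if isolated or minor_count == 0:
                return CloneVerdict(clone_id, f"clean_{major}", [], minor_count)

    # chimeric: alternating A/B segments, each spanning >= min_segment sites,
    # tolerating <= max_isolated isolated off-state positions in total
    ab_runs = [r for r in runs if (r[2] - r[1]) >= min_segment]
    merged: list[tuple[str, int, int]] = []
    for state, i, j in ab_runs:
        if merged and merged[-1][0] == state:
            merged[-1] = (state, merged[-1][1], j)
        else:
            merged.append((state, i, j))
    covered = sum(j - i for _, i, j in merged)
    stray = len(states) - covered - n_q
    if len(merged) >= 2 and stray <= max_isolated:
        switch_points = [j for (_, _, j) in merged[:-1]]
        return CloneVerdict(clone_id, "chimeric", switch_points, stray)

    return CloneVerdict(clone_id, "ambiguous", [], min(n_a, n_b) + n_q)


def assign_parental_origin(
    call: AlleleCall,
    parent_refs: dict[str, SequenceRecord],
) -> dict[str, str]:
    """Assign each haplotype to the parent it matches at a strict majority of
    parent-distinguishing sites; ``unresolved`` on tie or no distinguishing sites.

    ``parent_refs`` maps parent labels (e.g. ``Pm``, ``Pl``) to reference CDS.
    Sequences of unequal length are projected onto the longest via global
    alignment before comparison.
    """
    if len(parent_refs) != 2:
        raise ClonephaseError("exactly two parental references required")
    (name_a, ref_a), (name_b, ref_b) = parent_refs.items()

    out: dict[str, str] = {}
    for hap in call.haplotypes:
        seqs = {"hap": hap.ungapped(), name_a: ref_a, name_b: ref_b}
        proj = _project_to_anchor(seqs)
        cols = [
            i
            for i in range(len(proj[name_a]))
            if proj[name_a][i] != proj[name_b][i]
        ]
        if not cols:
            out[hap.id] = "unresolved"
            continue
        m_a = sum(1 for i in cols if proj["hap"][i] == proj[name_a][i])
        m_b = sum(1 for i in cols if proj["hap"][i] == proj[name_b][i])
        if m_a > m_b:
            out[hap.id] = name_a
        elif m_b > m_a:
            out[hap.id] = name_b
        else:
            out[hap.id] = "unresolved"
    return out


def _project_to_anchor(seqs: dict[str, SequenceRecord]) -> dict[str, str]:
    """Star-align all sequences to the longest; returns gapped strings."""
    anchor_key = max(seqs, key=lambda k: len(seqs[k]))
    anchor = seqs[anchor_key]
    out = {anchor_key: anchor.residues}
    for key, rec in seqs.items():
        if key == anchor_key:
            continue
        if len(rec) == len(anchor):
            out[key] = rec.residues
        else:
            aln = global_align(anchor, rec, codon_aware=True)
            if len(aln.a) != len(anchor):
                raise ClonephaseError(
                    f"sequence {rec.id} has insertions relative to the anchor; "
                    "inputs are not star-alignable"
                )
            out[key] = aln.b.residues
    return out


def single_allele_test(n_clones: int, observed: tuple[int, int]) -> AlleleDetectionTest:
    """Pearson χ² test of balanced allele sampling among cloned reads.

    Under the null that the individual is heterozygous and both alleles are
    sampled with probability 1/2, the expected clone split is (n/2, n/2).
    The statistic Σ(O−E)²/E with df=1 (no continuity correction) gives the
    upper-tail p-value; with observed (26, 0) this reproduces χ² = 26,
    P = 3.414e-07.
    """
    a, b = observed
    if n_clones <= 0:
        raise ClonephaseError("n_clones must be positive")
    if a + b != n_clones:
        raise ClonephaseError("observed counts must sum to n_clones")
    expected = n_clones / 2.0
    stat = (a - expected) ** 2 / expected + (b - expected) ** 2 / expected
    p = float(chi2.sf(stat, df=1))
    return AlleleDetectionTest(n_clones, (a, b), float(stat), 1, p)
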