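"""Simulate the "frozen hybrid" study design and every input the pipeline reads.

The genetic model: a clonal gynogenetic hybrid carries one allele of each
parental species at every locus, fixed in a heterozygous state since the
founding hybridization. Differences between the two parental species
("ancestral" polymorphisms) are therefore inherited intact as heterozygous
sites in the hybrid, while later mutations are private to one of the four
lineage sequences (Pm, Pf-allele1, Pf-allele2, Pl). The generator plants a
configurable number of ancestral differences per protein domain, lineage-
specific derived substitutions, codon-multiple indels, clone reads with
per-base error and PCR template-switch chimeras, qRT-PCR CT tables, and
homolog alignments for conservation profiling — together with a truth table
for parameter-recovery testing.

All randomness flows from ``rng_seed`` through named sub-streams (sequence,
clone errors, CT noise, homolog alignment), so partial reruns are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from clonephase.errors import ClonephaseError, ConfigError
from clonephase.phasing import CloneSet
from clonephase.seqcore import (
    GAP,
    SENSE_CODONS,
    STOP_CODONS,
    SequenceRecord,
    _CODON_TABLE,
    DomainInterval,
    DomainMap,
)

LINEAGES = ("Pm", "Pf1", "Pf2", "Pl")
NT = "ACGT"

# sub-stream ids for per-purpose generators derived from one seed
_STREAM_SEQ, _STREAM_CLONE, _STREAM_CT, _STREAM_HOMOLOG = 0, 1, 2, 3


class IndelEvent(BaseModel):
    model_config = ConfigDict(extra="forbid")

    aa_position: int  # first affected codon (deletion) / codon after which to insert
    length_nt: int
    kind: Literal["insertion", "deletion"]
    lineage: Literal["Pm", "Pf1", "Pf2", "Pl"]
    # events in a parental lineage predate the hybridization (the hybrid allele
    # of that origin inherits them) unless marked derived
    derived: bool = False

    @model_validator(mode="after")
    def _codon_multiple(self):
        if self.length_nt <= 0 or self.length_nt % 3 != 0:
            raise ValueError("indel length must be a positive multiple of 3")
        return self


class SimConfig(BaseModel):
    """Parameters of one simulated locus.

    Defaults mirror the study design: 12 clones sequenced for the hybrid and 6
    per bisexual ancestor, and an androgen-receptor-like domain architecture.
    """

    model_config = ConfigDict(extra="forbid")

    locus: str = "locusA"
    cds_length_nt: int = 2100
    domain_intervals: dict[str, tuple[int, int]] = Field(
        default_factory=lambda: {"NTD": (2, 430), "DBD": (431, 530), "LBD": (531, 699)}
    )
    n_ancestral_per_domain: dict[str, int] = Field(
        default_factory=lambda: {"NTD": 5, "DBD": 0, "LBD": 4}
    )
    nonsyn_fraction: float = 0.5
    n_derived: dict[str, int] = Field(
        default_factory=lambda: {"Pm": 0, "Pf1": 0, "Pf2": 0, "Pl": 0}
    )
    indel_events: list[IndelEvent] = Field(default_factory=list)
    clone_counts: dict[str, int] = Field(
        default_factory=lambda: {"Pf": 12, "Pm": 6, "Pl": 6}
    )
    base_error_rate: float = 1e-3
    chimera_rate: float = 0.0
    single_allele_mode: Optional[Literal["Pm", "Pl"]] = None
    rng_seed: int = 0

    @model_validator(mode="after")
    def _validate(self):
        if self.cds_length_nt % 3 != 0 or self.cds_length_nt < 9:
            raise ValueError("cds_length_nt must be a multiple of 3 and >= 9")
        n_aa = self.cds_length_nt // 3 - 1  # last codon is the stop
        prev_end = 0
        for name, (start, end) in sorted(
            self.domain_intervals.items(), key=lambda kv: kv[1][0]
        ):
            if start < 1 or end > n_aa or end < start:
                raise ValueError(f"domain {name} outside coding range 1..{n_aa}")
            if start <= prev_end:
                raise ValueError(f"domain {name} overlaps the previous domain")
            prev_end = end
        for name in self.n_ancestral_per_domain:
            if name not in self.domain_intervals:
                raise ValueError(f"ancestral counts given for unknown domain {name}")
        for lin in self.n_derived:
            if lin not in LINEAGES:
                raise ValueError(f"unknown lineage {lin} in n_derived")
        if not 0 <= self.base_error_rate < 1 or not 0 <= self.chimera_rate <= 1:
            raise ValueError("rates must be probabilities")
        return self

    def domain_map(self) -> DomainMap:
        return DomainMap(
            self.locus,
            [DomainInterval(n, s, e) for n, (s, e) in self.domain_intervals.items()],
        )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.rng_seed), int(stream)])


@dataclass
class PlantedSite:
    """Internal bookkeeping of one planted substitution (ancestor codon frame)."""

    codon_idx: int  # 1-based ancestor codon
    offset: int  # 0..2 within the codon
    codons: dict[str, str]  # final codon per lineage tag
    polarity: str
    coding_effect: str
    domain: str


@dataclass
class HybridTruth:
    """Ground truth for one simulated locus."""

    config: SimConfig
    ancestor_codons: list[str]
    founder_codons: dict[str, list[str]]  # Pm/Pl at hybridization time
    lineage_codons: dict[str, list[Optional[str]]] = field(default_factory=dict)
    insertions: dict[str, dict[int, list[str]]] = field(default_factory=dict)
    sites: list[PlantedSite] = field(default_factory=list)
    indels: list[IndelEvent] = field(default_factory=list)
    hybrid_origins: dict[str, str] = field(default_factory=dict)  # allele tag -> parent

    # -- sequence assembly ---------------------------------------------------

    def lineage_tags(self) -> list[str]:
        if self.config.single_allele_mode:
            only = "Pf1" if self.config.single_allele_mode == "Pm" else "Pf2"
            return ["Pm", only, "Pl"]
        return list(LINEAGES)

    def sequence(self, tag: str) -> SequenceRecord:
        codons = self.lineage_codons[tag]
        ins = self.insertions.get(tag, {})
        parts = list(ins.get(0, []))
        for i, codon in enumerate(codons, start=1):
            if codon is not None:
                parts.append(codon)
            parts.extend(ins.get(i, []))
        return SequenceRecord(f"{self.config.locus}_{tag}", "".join(parts), "nt")

    @property
    def parental_haplotypes(self) -> dict[str, SequenceRecord]:
        return {tag: self.sequence(tag) for tag in ("Pm", "Pl")}

    @property
    def hybrid_alleles(self) -> dict[str, SequenceRecord]:
        return {tag: self.sequence(tag) for tag in self.lineage_tags() if tag.startswith("Pf")}

    def aligned_quartet(self) -> dict[str, SequenceRecord]:
        """The true multiple alignment of the (3 or 4) lineage sequences."""
        tags = self.lineage_tags()
        all_ins_points = sorted(
            {p for tag in tags for p in self.insertions.get(tag, {})}
        )
        out = {tag: [] for tag in tags}

        def emit_insertions(point: int) -> None:
            for tag in tags:
                block = self.insertions.get(tag, {}).get(point, [])
                width = max(
                    len(self.insertions.get(t, {}).get(point, [])) for t in tags
                )
                padded = block + ["---"] * (width - len(block))
                out[tag].extend(padded)

        if 0 in all_ins_points:
            emit_insertions(0)
        for i in range(1, len(self.ancestor_codons) + 1):
            for tag in tags:
                codon = self.lineage_codons[tag][i - 1]
                out[tag].append(codon if codon is not None else "---")
            if i in all_ins_points:
                emit_insertions(i)
        return {
            tag: SequenceRecord(f"{self.config.locus}_{tag}", "".join(out[tag]), "nt")
            for tag in tags
        }

    # -- coordinate mapping ---------------------------------------------------

    def truth_table(self) -> pd.DataFrame:
        """Planted sites and indels in naming-reference (Pl) coordinates.

        Rows are produced by classifying the true (noise-free) lineage
        sequences with the same representation code the detector applies to
        reconstructed sequences. Where an event admits several equivalent
        placements — an indel in a repeat, or an indel flanked by a
        substitution — both sides therefore land on the identical canonical
        form, and recovery can be scored by exact row comparison.
        """
        from clonephase import polyclass as pc  # deferred: keeps synthdata importable alone

        seqs = {}
        for tag in self.lineage_tags():
            key = "Pf" if self.config.single_allele_mode and tag.startswith("Pf") else tag
            rec = self.sequence(tag)
            seqs[key] = SequenceRecord(f"{self.config.locus}_{key}", rec.residues, "nt")
        quartet = pc.build_quartet(self.config.locus, seqs)
        sites = pc.detect_polymorphisms(quartet, self.config.domain_map())
        return pc.sites_to_frame(sites, self.config.locus)


def _indel_carriers(ev: IndelEvent) -> set[str]:
    if ev.lineage in ("Pf1", "Pf2"):
        return {ev.lineage}
    if ev.derived:
        return {ev.lineage}
    return {"Pm", "Pf1"} if ev.lineage == "Pm" else {"Pl", "Pf2"}


# ---------------------------------------------------------------------------
# Stage 1: parental haplotypes with ancestral differences


def _random_cds(n_codons: int, rng: np.random.Generator) -> list[str]:
    body = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons - 2)]
    return ["ATG"] + body + ["TAA"]


def _single_nt_variants(codon: str) -> list[tuple[int, str]]:
    out = []
    for off in range(3):
        for b in NT:
            if b != codon[off]:
                cand = codon[:off] + b + codon[off + 1 :]
                if cand not in STOP_CODONS:
                    out.append((off, cand))
    return out


def _variants_of_type(codon: str, synonymous: bool) -> list[tuple[int, str]]:
    aa = _CODON_TABLE[codon]
    return [
        (off, cand)
        for off, cand in _single_nt_variants(codon)
        if (_CODON_TABLE[cand] == aa) == synonymous
    ]


def generate_parental_haplotypes(config: SimConfig) -> HybridTruth:
    """Random CDS plus the configured ancestral differences per domain.

    Each ancestral site is a single-nucleotide difference between the Pm and Pl
    founder haplotypes, synonymous or non-synonymous according to
    ``nonsyn_fraction``. Codons are rejection-sampled so that no planted change
    creates a stop codon. Ancestral (pre-hybridization) indels from
    ``indel_events`` are recorded now and materialized with the rest in
    :func:`generate_hybrid_genotype`.
    """
    rng = config.rng(_STREAM_SEQ)
    n_codons = config.cds_length_nt // 3
    ancestor = _random_cds(n_codons, rng)
    dmap = config.domain_map()

    blocked: set[int] = {1, n_codons}
    for ev in config.indel_events:
        if ev.kind == "deletion":
            span = range(ev.aa_position, ev.aa_position + ev.length_nt // 3)
            if span.start < 2 or span.stop > n_codons:
                raise ConfigError(f"deletion {ev} outside coding range")
            blocked.update(span)
        else:
            if not 0 <= ev.aa_position <= n_codons - 1:
                raise ConfigError(f"insertion point {ev.aa_position} out of range")

    truth = HybridTruth(config=config, ancestor_codons=ancestor, founder_codons={})
    used: set[int] = set(blocked)

    for name, count in config.n_ancestral_per_domain.items():
        start, end = config.domain_intervals[name]
        candidates = [c for c in range(start, end + 1) if c not in used]
        if count > len(candidates):
            raise ConfigError(
                f"cannot place {count} ancestral sites in domain {name} "
                f"({len(candidates)} free codons)"
            )
        chosen = rng.choice(len(candidates), size=count, replace=False)
        for k in sorted(int(i) for i in chosen):
            c = candidates[k]
            used.add(c)
            synonymous = rng.random() >= config.nonsyn_fraction
            off, alt = _plant_variant(ancestor, c, synonymous, rng)
            # randomly decide which founder carries the alternative state
            pm_codon, pl_codon = (
                (alt, ancestor[c - 1]) if rng.random() < 0.5 else (ancestor[c - 1], alt)
            )
            truth.sites.append(
                PlantedSite(
                    codon_idx=c,
                    offset=off,
                    codons={"Pm": pm_codon, "Pf1": pm_codon, "Pf2": pl_codon, "Pl": pl_codon},
                    polarity="ancestral",
                    coding_effect="synonymous" if synonymous else "nonsynonymous",
                    domain=name,
                )
            )

    founder_pm = list(ancestor)
    founder_pl = list(ancestor)
    for s in truth.sites:
        founder_pm[s.codon_idx - 1] = s.codons["Pm"]
        founder_pl[s.codon_idx - 1] = s.codons["Pl"]
    truth.founder_codons = {"Pm": founder_pm, "Pl": founder_pl}
    truth._used_codons = used  # type: ignore[attr-defined]
    return truth


def _plant_variant(
    ancestor: list[str], codon_idx: int, synonymous: bool, rng: np.random.Generator
) -> tuple[int, str]:
    """Pick a single-nt variant of the desired type, resampling the ancestor
    codon if it admits none (e.g. ATG/TGG have no synonymous variant)."""
    for _ in range(1000):
        codon = ancestor[codon_idx - 1]
        options = _variants_of_type(codon, synonymous)
        if options:
            off, alt = options[int(rng.integers(0, len(options)))]
            return off, alt
        ancestor[codon_idx - 1] = SENSE_CODONS[int(rng.integers(0, len(SENSE_CODONS)))]
    raise ConfigError("failed to place a variant (rejection sampling exhausted)")


# ---------------------------------------------------------------------------
# Stage 2: hybrid genotype + derived mutations + indels


def generate_hybrid_genotype(truth: HybridTruth, config: SimConfig) -> HybridTruth:
    """Copy founder haplotypes into the hybrid, then plant derived mutations and
    materialize indel events.

    In ``single_allele_mode`` the hybrid retains only the allele of the named
    parental origin (the *erβ1* situation), and truth-table polarity labels are
    projected to the trio (Pm-Pf-Pl) interpretation.
    """
    if not truth.founder_codons:
        raise ClonephaseError("generate_parental_haplotypes must run first")
    # stage 2 draws from its own child stream so the stages compose
    # deterministically regardless of how many draws stage 1 consumed
    rng = np.random.default_rng([int(config.rng_seed), _STREAM_SEQ, 1])
    n_codons = len(truth.ancestor_codons)

    lineage: dict[str, list[Optional[str]]] = {
        "Pm": list(truth.founder_codons["Pm"]),
        "Pf1": list(truth.founder_codons["Pm"]),
        "Pf2": list(truth.founder_codons["Pl"]),
        "Pl": list(truth.founder_codons["Pl"]),
    }
    truth.hybrid_origins = {"Pf1": "Pm", "Pf2": "Pl"}

    used: set[int] = set(getattr(truth, "_used_codons", {1, n_codons}))
    dmap = config.domain_map()

    active = truth.lineage_tags()
    for lin in LINEAGES:
        count = config.n_derived.get(lin, 0)
        if lin not in active:
            continue
        for _ in range(count):
            candidates = [c for c in range(2, n_codons) if c not in used]
            if not candidates:
                raise ConfigError("no free codons left for derived mutations")
            c = candidates[int(rng.integers(0, len(candidates)))]
            used.add(c)
            synonymous = rng.random() >= config.nonsyn_fraction
            base = lineage[lin][c - 1]
            options = _variants_of_type(base, synonymous)
            if not options:
                options = _single_nt_variants(base)
                synonymous = _CODON_TABLE[options[0][1]] == _CODON_TABLE[base]
            off, alt = options[int(rng.integers(0, len(options)))]
            lineage[lin][c - 1] = alt
            codons = {t: lineage[t][c - 1] for t in LINEAGES}
            truth.sites.append(
                PlantedSite(
                    codon_idx=c,
                    offset=off,
                    codons=codons,
                    polarity=f"derived_in_{lin}",
                    coding_effect="synonymous" if synonymous else "nonsynonymous",
                    domain=dmap.domain_of(c),
                )
            )

    # normalize Pf polarity tags
    for s in truth.sites:
        if s.polarity in ("derived_in_Pf1", "derived_in_Pf2"):
            s.polarity = "derived_in_Pf"

    # indels
    insertions: dict[str, dict[int, list[str]]] = {t: {} for t in LINEAGES}
    for ev in config.indel_events:
        carriers = _indel_carriers(ev)
        n_del = ev.length_nt // 3
        if ev.kind == "deletion":
            for t in carriers:
                for c in range(ev.aa_position, ev.aa_position + n_del):
                    lineage[t][c - 1] = None
        else:
            ins = [
                SENSE_CODONS[int(rng.integers(0, len(SENSE_CODONS)))]
                for _ in range(n_del)
            ]
            for t in carriers:
                insertions[t].setdefault(ev.aa_position, []).extend(ins)
        truth.indels.append(ev)

    truth.lineage_codons = lineage
    truth.insertions = insertions
    return truth


def simulate_locus(config: SimConfig) -> HybridTruth:
    """Convenience: both generation stages."""
    return generate_hybrid_genotype(generate_parental_haplotypes(config), config)


# ---------------------------------------------------------------------------
# Clone reads


def generate_clone_reads(
    alleles: list[SequenceRecord],
    n_clones: int,
    base_error_rate: float,
    chimera_rate: float,
    rng: np.random.Generator,
    species: str = "Pf",
    individual: str = "i1",
    locus: str = "locusA",
) -> tuple[CloneSet, pd.DataFrame]:
    """Draw clones from 1 or 2 alleles with per-base error and template switches.

    Each clone derives from one allele chosen with probability 1/2 (single
    allele: always that allele); with probability ``chimera_rate`` the clone is
    instead a single-crossover recombinant of the two alleles at a breakpoint
    uniform over alignment columns. Truth labels (source allele or ``chimera``
    plus breakpoint) are returned alongside.

    With two alleles the clone set is conditioned on each allele appearing in
    at least two non-chimeric clones (when enough non-chimeric clones exist):
    heterozygosity is established from double peaks in the direct sequencing
    chromatogram before cloning, variants are only accepted when confirmed in
    multiple clones, and a batch that under-sampled one allele would be topped
    up at the bench rather than analysed as-is.
    """
    if not 1 <= len(alleles) <= 2:
        raise ConfigError("1 or 2 alleles required")
    if len(alleles) == 1 and chimera_rate > 0:
        raise ConfigError("chimeras require two alleles")

    if len(alleles) == 2 and len(alleles[0]) != len(alleles[1]):
        from clonephase.seqcore import global_align

        aln = global_align(alleles[0], alleles[1], codon_aware=True)
        aligned = [aln.a.residues, aln.b.residues]
    else:
        aligned = [a.residues for a in alleles]

    width = len(aligned[0])

    def draw_plan() -> list[tuple[str, int]]:
        plan = []
        for _ in range(n_clones):
            if len(aligned) == 2 and rng.random() < chimera_rate:
                bp = int(rng.integers(1, width))
                first = 0 if rng.random() < 0.5 else 1
                plan.append(("chimera", bp, first))
            else:
                plan.append(("allele", int(rng.integers(0, len(aligned))), -1))
        return plan

    plan = draw_plan()
    if len(aligned) == 2:
        # condition on >= 2 non-chimeric clones per allele (see above)
        for _ in range(10_000):
            choices = [c[1] for c in plan if c[0] == "allele"]
            need = 2 if len(choices) >= 4 else 1 if len(choices) >= 2 else 0
            if choices.count(0) >= need and choices.count(1) >= need:
                break
            plan = draw_plan()
        else:  # pragma: no cover - vanishing redraw probability per attempt
            raise ConfigError("could not sample both alleles; check clone design")

    clones = []
    labels = []
    for k, entry in enumerate(plan):
        cid = f"{species}.{individual}.{locus}.c{k + 1:02d}"
        if entry[0] == "chimera":
            _, bp, first = entry
            i, j = (0, 1) if first == 0 else (1, 0)
            seq = aligned[i][:bp] + aligned[j][bp:]
            source = "chimera"
        else:
            _, i, bp = entry
            seq = aligned[i]
            source = f"allele{i + 1}"
        seq = seq.replace(GAP, "")
        seq = _apply_errors(seq, base_error_rate, rng)
        clones.append(SequenceRecord(cid, seq, "nt"))
        labels.append({"clone_id": cid, "source": source, "breakpoint_col": bp})
    return (
        CloneSet(locus=locus, species=species, individual=individual, clones=clones),
        pd.DataFrame(labels),
    )


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        cur = arr[i].decode()
        choices = [b for b in NT if b != cur]
        arr[i] = choices[int(rng.integers(0, 3))].encode()
    return arr.tobytes().decode()


def clone_sets_for_truth(
    truth: HybridTruth, rng: np.random.Generator | None = None
) -> dict[str, CloneSet]:
    """Clone sets for the hybrid and both parents under the configured design."""
    cfg = truth.config
    if rng is None:
        rng = cfg.rng(_STREAM_CLONE)
    out = {}
    hyb = list(truth.hybrid_alleles.values())
    cs, labels = generate_clone_reads(
        hyb, cfg.clone_counts.get("Pf", 12), cfg.base_error_rate, cfg.chimera_rate,
        rng, species="Pf", individual="i1", locus=cfg.locus,
    )
    cs.truth_labels = labels  # type: ignore[attr-defined]
    out["Pf"] = cs
    for parent in ("Pm", "Pl"):
        cs, labels = generate_clone_reads(
            [truth.sequence(parent)], cfg.clone_counts.get(parent, 6),
            cfg.base_error_rate, 0.0, rng, species=parent, individual="i1",
            locus=cfg.locus,
        )
        cs.truth_labels = labels  # type: ignore[attr-defined]
        out[parent] = cs
    return out


# ---------------------------------------------------------------------------
# qRT-PCR CT tables


@dataclass
class CtGroupSpec:
    species: str
    tissue: str
    gene: str
    mean_dct: float  # true mean CT difference vs the reference gene
    bio_sd: float = 0.5
    tech_sd: float = 0.15
    detected: bool = True


@dataclass
class CtDesign:
    """Design of a simulated qRT-PCR experiment.

    The reference gene is simulated with low biological variance around
    ``ref_ct_mean``; each target gene's CT for an individual is the
    individual's reference CT plus the group's true ΔCT plus biological noise,
    and technical replicates add instrument noise. Conditions whose true CT
    exceeds the detection ceiling — or flagged ``detected=False`` — yield
    non-detect CT values above 35 (the literal instrument readout; filtering
    happens downstream).
    """

    groups: list[CtGroupSpec]
    reference_gene: str = "rpl7"
    ref_ct_mean: float = 20.0
    ref_bio_sd: float = 0.2
    ref_tech_sd: float = 0.15
    n_individuals: int = 4
    n_replicates: int = 3
    detection_ceiling: float = 35.0

    @classmethod
    def balanced(
        cls,
        species: list[str],
        tissues: list[str],
        genes: list[str],
        mean_dct: float = 5.0,
        bio_sd: float = 0.5,
        tech_sd: float = 0.15,
        **kwargs,
    ) -> "CtDesign":
        groups = [
            CtGroupSpec(s, t, g, mean_dct, bio_sd, tech_sd)
            for s in species
            for t in tissues
            for g in genes
        ]
        return cls(groups=groups, **kwargs)

    def group(self, species: str, tissue: str, gene: str) -> CtGroupSpec:
        for g in self.groups:
            if (g.species, g.tissue, g.gene) == (species, tissue, gene):
                return g
        raise KeyError((species, tissue, gene))


def generate_ct_table(design: CtDesign, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Long-format CT table: species, tissue, individual, gene, tech_replicate, ct."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng([int(seed), _STREAM_CT])
    )
    rows = []
    cells = sorted({(g.species, g.tissue) for g in design.groups})
    for sp, ti in cells:
        specs = [g for g in design.groups if (g.species, g.tissue) == (sp, ti)]
        for ind in range(1, design.n_individuals + 1):
            ind_id = f"{sp}_{ti}_ind{ind}"
            ref_ct = design.ref_ct_mean + rng.normal(0.0, design.ref_bio_sd)
            for rep in range(1, design.n_replicates + 1):
                rows.append(
                    {
                        "species": sp,
                        "tissue": ti,
                        "individual": ind_id,
                        "gene": design.reference_gene,
                        "tech_replicate": rep,
                        "ct": round(ref_ct + rng.normal(0.0, design.ref_tech_sd), 4),
                    }
                )
            for g in specs:
                true_ct = ref_ct + g.mean_dct + rng.normal(0.0, g.bio_sd)
                for rep in range(1, design.n_replicates + 1):
                    if not g.detected or true_ct > design.detection_ceiling:
                        ct = design.detection_ceiling + 1.0 + 4.0 * rng.random()
                    else:
                        ct = true_ct + rng.normal(0.0, g.tech_sd)
                    rows.append(
                        {
                            "species": sp,
                            "tissue": ti,
                            "individual": ind_id,
                            "gene": g.gene,
                            "tech_replicate": rep,
                            "ct": round(float(ct), 4),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Homolog alignments for conservation profiling


def generate_homolog_alignment(
    n_taxa: int,
    column_profiles: list[tuple[str, float]],
    seed: int | np.random.Generator = 0,
) -> list[SequenceRecord]:
    """Amino-acid alignment whose per-column major-residue frequencies converge
    to the given profiles as ``n_taxa`` grows.

    Each profile is ``(major_residue, frequency)`` with frequency in (0, 1];
    minor residues are drawn uniformly from the remaining 19 amino acids.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng([int(seed), _STREAM_HOMOLOG])
    )
    aa20 = "ACDEFGHIKLMNPQRSTVWY"
    for res, freq in column_profiles:
        if not 0 < freq <= 1:
            raise ConfigError(f"major-residue frequency {freq} outside (0, 1]")
        if res not in aa20:
            raise ConfigError(f"unknown residue {res!r}")
    cols = []
    for res, freq in column_profiles:
        minors = [a for a in aa20 if a != res]
        draw = rng.random(n_taxa)
        col = np.where(
            draw < freq, res, np.array(minors)[rng.integers(0, 19, n_taxa)]
        )
        cols.append(col)
    mat = np.array(cols).T
    return [
        SequenceRecord(f"taxon{i + 1}", "".join(mat[i]), "aa") for i in range(n_taxa)
    ]


# ---------------------------------------------------------------------------
# Presets mirroring the study's locus architectures


def preset_config(name: str, seed: int = 0) -> SimConfig:
    """Named locus scenarios.

    * ``ar_alpha`` — 9 ancestral differences (5 NTD, 0 DBD, 4 LBD) and a few
      lineage-private substitutions; the heterozygous two-allele architecture.
    * ``ar_beta``  — 10 ancestral differences across all three domains plus a
      6-nt ancestral deletion in the Pm lineage.
    * ``er_beta1`` — single hybrid allele of Pl origin (trio mode) with
      Pm-private substitutions.
    * ``dense``    — many ancestral sites; used for chimera-detector evaluation
      where informative-site density matters.
    """
    presets = {
        "ar_alpha": dict(
            locus="ar_alpha",
            n_ancestral_per_domain={"NTD": 5, "DBD": 0, "LBD": 4},
            n_derived={"Pm": 2, "Pf1": 2, "Pf2": 1, "Pl": 0},
        ),
        "ar_beta": dict(
            locus="ar_beta",
            n_ancestral_per_domain={"NTD": 6, "DBD": 1, "LBD": 3},
            n_derived={"Pm": 1, "Pf1": 1, "Pf2": 0, "Pl": 0},
            indel_events=[
                IndelEvent(aa_position=240, length_nt=6, kind="deletion", lineage="Pm")
            ],
        ),
        "er_beta1": dict(
            locus="er_beta1",
            n_ancestral_per_domain={"NTD": 2, "DBD": 0, "LBD": 2},
            n_derived={"Pm": 3, "Pf2": 1, "Pl": 1},
            single_allele_mode="Pl",
            clone_counts={"Pf": 26, "Pm": 6, "Pl": 6},
        ),
        "dense": dict(
            locus="dense",
            n_ancestral_per_domain={"NTD": 30, "DBD": 10, "LBD": 40},
            n_derived={},
        ),
    }
    if name not in presets:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return SimConfig(rng_seed=seed, **presets[name])


# ---------------------------------------------------------------------------
# File output


def write_truth_table(truth: HybridTruth, path: str | Path) -> None:
    truth.truth_table().to_csv(path, sep="\t", index=False)


def write_ct_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
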