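"""A locus at which the hybrid carries only one ancestral allele.

26 clones are sequenced and every one shows the same haplotype. The χ² sampling
test asks whether that is plausible for a heterozygote whose two alleles are
amplified evenly — with 26:0 it is not, and the locus is called single-allele.
Site classification then runs in trio mode (Pm, hybrid, Pl), where an
ancestral-versus-Pm-private distinction is no longer observable.
"""

from clonephase import phasing as ph
from clonephase import polyclass as pc
from clonephase import synthdata as sd

cfg = sd.preset_config("er_beta1", seed=7)
truth = sd.simulate_locus(cfg)
clone_sets = sd.clone_sets_for_truth(truth)

call = ph.infer_alleles(clone_sets["Pf"])
print(f"haplotypes called : {len(call.haplotypes)} (from {sum(call.support)} clones)")

test = ph.single_allele_test(sum(call.support), (call.support[0], 0))
print(f"chi-square        : {test.chi2:.0f} (df={test.df})")
print(f"P                 : {test.p_value:.3E}")

pm_ref = ph.infer_alleles(clone_sets["Pm"]).ungapped_haplotypes()[0]
pl_ref = ph.infer_alleles(clone_sets["Pl"]).ungapped_haplotypes()[0]
refs = {"Pm": pm_ref, "Pl": pl_ref}
origins = ph.assign_parental_origin(call, refs)
print(f"allele origin     : {list(origins.values())[0]}")

quartet = pc.quartet_from_phasing(cfg.locus, call, origins, refs)
sites = pc.detect_polymorphisms(quartet, cfg.domain_map())
frame = pc.sites_to_frame(sites, cfg.locus)
print("\ntrio-mode site classification:")
print(frame[["nt_site", "polarity", "coding_effect", "domain", "code"]].to_string(index=False))
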