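import numpy as np
import pytest

from clonephase import synthdata as sd


@pytest.fixture
def ar_alpha_truth():
    cfg = sd.preset_config("ar_alpha", seed=1).model_copy(
        update={"base_error_rate": 0.0, "chimera_rate": 0.0}
    )
    return sd.simulate_locus(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def run_pipeline(truth):
    """Clone -> phase -> classify chain used by several tests."""
    from clonephase import phasing as ph
    from clonephase import polyclass as pc

    cfg = truth.config
    sets = sd.clone_sets_for_truth(truth)
    call = ph.infer_alleles(sets["Pf"])
    pm_ref = ph.infer_alleles(sets["Pm"]).ungapped_haplotypes()[0]
    pl_ref = ph.infer_alleles(sets["Pl"]).ungapped_haplotypes()[0]
    refs = {"Pm": pm_ref, "Pl": pl_ref}
    origins = ph.assign_parental_origin(call, refs)
    quartet = pc.quartet_from_phasing(cfg.locus, call, origins, refs)
    sites = pc.detect_polymorphisms(quartet, cfg.domain_map())
    return call, origins, sites
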