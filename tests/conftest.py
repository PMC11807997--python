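import pytest

from uromet import CohortSpec, PipelineConfig, generate_cohort
from uromet.io import COMPARISONS
from uromet.preprocess import preprocess_table
from uromet.screen import screen_comparison


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (62/43/57, 200 features, 20 planted effects
    per comparison at FC 2.0/0.5), fixed seed."""
    spec = CohortSpec(seed=11)
    neg, pos, meta, pmap, truth = generate_cohort(spec)
    return {"spec": spec, "neg": neg, "pos": pos, "metadata": meta,
            "pathway_map": pmap, "truth": truth}


@pytest.fixture(scope="session")
def clean(cohort):
    """Cohort after QC CV filtering and group-wise KNN imputation."""
    tables, qc_reports, imp_reports = {}, {}, {}
    for t in (cohort["neg"], cohort["pos"]):
        tables[t.ion_mode], qc_reports[t.ion_mode], imp_reports[t.ion_mode] = \
            preprocess_table(t, cohort["metadata"])
    return {**cohort, "tables": tables, "qc_reports": qc_reports,
            "imputation_reports": imp_reports}


@pytest.fixture(scope="session")
def screens(clean):
    """The three pairwise OPLS-DA screens on the cleaned cohort."""
    config = PipelineConfig(seed=11)
    return {
        comp.name: screen_comparison(
            clean["tables"]["negative"], clean["tables"]["positive"],
            clean["metadata"], comp, config, compute_q2=True)
        for comp in COMPARISONS
    }
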