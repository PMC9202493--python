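from pathlib import Path

import pytest

from comorbnet import preprocess, synthetic_data


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A 3,000-case synthetic corpus with its file bundle on disk."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = synthetic_data.ReportGenConfig(n_cases=3_000, rng_seed=11)
    reports, truth = synthetic_data.generate_case_reports(cfg, out)
    return {"dir": Path(out), "config": cfg, "reports": reports, "truth": truth}


@pytest.fixture(scope="session")
def small_cases(small_bundle):
    """The small bundle pushed through the full preprocessing chain."""
    out = small_bundle["dir"]
    tables = preprocess.read_faers_tables(out)
    tables, _ = preprocess.deduplicate_cases(tables)
    maps = {
        name: preprocess.load_vocabulary(out / f"{name}_map.tsv")
        for name in ("drug", "indi", "reac")
    }
    tables, _ = preprocess.normalize_terms(tables, maps)
    cases = preprocess.assemble_cases(tables)
    lexicon = preprocess.load_lexicon(out / "lexicon.tsv")
    cases, n_flagged = preprocess.flag_oud_cases(cases, lexicon)
    return {"cases": cases, "n_flagged": n_flagged, "lexicon": lexicon}
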