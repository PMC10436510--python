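import numpy as np
import pytest

from p450screen.reference import demo_config, panel_to_bed
from p450screen.synthetic import generate_cohort, write_subject_table, write_vcf


@pytest.fixture(scope="session")
def demo():
    """The packaged demo study: config, panel and reference manifest."""
    return demo_config(seed=7)


@pytest.fixture(scope="session")
def demo_cohort(demo):
    config, _, _ = demo
    return generate_cohort(config)


@pytest.fixture(scope="session")
def demo_paths(tmp_path_factory, demo, demo_cohort):
    """Demo study written to disk: cohort.vcf, subjects.tsv, panel.bed."""
    config, panel, _ = demo
    out = tmp_path_factory.mktemp("demo")
    write_vcf(demo_cohort, out / "cohort.vcf")
    write_subject_table(demo_cohort, out / "subjects.tsv")
    panel_to_bed(panel, out / "panel.bed")
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20240601)
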