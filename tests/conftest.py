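import pytest

from forenstr import fixtures as fx


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 30-donor cohort with metadata and its locus specs."""
    spec = fx.default_cohort_spec(seed=11, n_samples=30)
    records, people = fx.generate_cohort(spec)
    return spec, records, people


@pytest.fixture(scope="session")
def motif_specs(small_cohort):
    spec, _, _ = small_cohort
    return [l.motif_spec() for l in spec.loci]
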