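import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dacmet import FeatureTable, Peak, RunConfig, SampleDesign, run_all
from dacmet.synth import subnetwork_a_fixture

settings.register_profile(
    "default", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def make_table(rows, samples):
    """Build a FeatureTable from (peak_id, ion_mode, neutral_mass, rt,
    {sample: intensity}) tuples."""
    peaks, data = [], []
    for peak_id, mode, mass, rt, intens in rows:
        sign = 1.0 if mode == "positive" else -1.0
        adduct = "[M+H]+" if mode == "positive" else "[M-H]-"
        peaks.append(Peak(peak_id, mode, mass + sign * 1.007276, adduct, rt, mass))
        data.append([intens.get(s, np.nan) for s in samples])
    intensity = pd.DataFrame(
        data, index=pd.Index([p.peak_id for p in peaks], name="peak_id"),
        columns=samples)
    return FeatureTable(peaks, intensity)


def make_design(n_subjects=4, timepoints=(0.25, 0.5, 1, 2, 4, 8),
                n_mock=2, extract=True, herbs=()):
    rows = []
    for i in range(n_subjects):
        subj = f"S{i + 1}"
        rows.append(dict(sample_id=f"{subj}_pre", subject=subj, cls="pre",
                         timepoint=np.nan, herb=""))
        for tp in timepoints:
            rows.append(dict(sample_id=f"{subj}_{tp:g}h", subject=subj,
                             cls="post", timepoint=tp, herb=""))
    for j in range(n_mock):
        rows.append(dict(sample_id=f"MOCK{j + 1}", subject="mock", cls="mock",
                         timepoint=np.nan, herb=""))
    if extract:
        rows.append(dict(sample_id="EXTRACT", subject="extract", cls="extract",
                         timepoint=np.nan, herb=""))
    for herb in herbs:
        rows.append(dict(sample_id=f"HERB_{herb}", subject=f"rat_{herb}",
                         cls="herb_plasma", timepoint=np.nan, herb=herb))
    df = pd.DataFrame(rows).rename(columns={"cls": "class"})
    return SampleDesign(df)


@pytest.fixture(scope="session")
def subnet_fixture():
    return subnetwork_a_fixture()


@pytest.fixture(scope="session")
def subnet_result(subnet_fixture):
    fx = subnet_fixture
    config = RunConfig(merge_exceptions=(("P2001", "P2002"),))
    return run_all(fx.feature_table, fx.design, config,
                   annotations=fx.annotations, msms=fx.msms,
                   isotopes=fx.isotopes)
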