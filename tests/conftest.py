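import pandas as pd
import pytest
from hypothesis import settings

from gliprio.harmonize_meta import CohortGliStat

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_stat(**overrides) -> CohortGliStat:
    """CohortGliStat factory with sensible defaults for single-field tweaks."""
    base = dict(
        variant_id="rs1",
        chrom="chr1",
        pos=1_000_000,
        effect_allele="A",
        other_allele="G",
        eaf=0.3,
        n=1000,
        beta_G=0.1,
        se_G=0.05,
        beta_GL=0.2,
        se_GL=0.08,
        cov_G_GL=0.0,
        ancestry="EA",
        trait="HDL",
        exposure="current smoking",
        cohort_id="cohort1",
    )
    base.update(overrides)
    return CohortGliStat(**base)


@pytest.fixture
def stat_factory():
    return make_stat


def make_selected(rows) -> pd.DataFrame:
    """Build a selected-variants frame from (variant_id, chrom, pos, trait,
    exposure, ancestry_group) tuples, with optional trailing p_joint."""
    recs = []
    for r in rows:
        rec = dict(
            zip(
                ["variant_id", "chrom", "pos", "trait", "exposure", "ancestry_group"],
                r[:6],
            )
        )
        rec["p_int"] = 1e-6
        rec["p_joint"] = r[6] if len(r) > 6 else 1.0
        recs.append(rec)
    return pd.DataFrame(recs)


@pytest.fixture
def selected_factory():
    return make_selected
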