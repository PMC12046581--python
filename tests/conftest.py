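import numpy as np
import pandas as pd
import pytest

from drugtarget_mr.io import SUMMARY_COLUMNS, SummaryTable


def make_table(rows, trait_name="trait", trait_type="quantitative",
               trait_units=""):
    """Build a SummaryTable from a list of dicts, filling canonical defaults."""
    defaults = {"chrom": "1", "effect_allele": "A", "other_allele": "G",
                "eaf": 0.3, "n": 100000.0, "n_cases": np.nan}
    full = []
    for i, row in enumerate(rows):
        r = dict(defaults)
        r.setdefault("pos", (i + 1) * 1000)
        r.update(row)
        full.append(r)
    df = pd.DataFrame(full)
    for c in SUMMARY_COLUMNS:
        if c not in df.columns:
            df[c] = defaults.get(c, np.nan)
    return SummaryTable(trait_name, trait_type, df[SUMMARY_COLUMNS],
                        trait_units)


@pytest.fixture
def three_snp_table():
    return make_table([
        {"snp_id": "rs1", "pos": 1000, "beta": 0.5, "se": 0.05, "pval": 1e-9},
        {"snp_id": "rs2", "pos": 2000, "beta": 0.3, "se": 0.05, "pval": 1e-8},
        {"snp_id": "rs3", "pos": 3000, "beta": -0.2, "se": 0.05, "pval": 1e-5},
    ])
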