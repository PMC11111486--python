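"""Shared builders for summary-statistic tables and harmonized instruments."""

import numpy as np
import pandas as pd
import pytest

from mrcausal.gwas_io import AssociationTable


ROW_DEFAULTS = {
    "chromosome": "1",
    "position": 1_000_000,
    "effect_allele": "A",
    "other_allele": "G",
    "eaf": 0.3,
    "beta": 0.1,
    "se": 0.01,
    "pval": 1e-10,
    "n": 50_000,
}


def make_table(rows, trait_type="continuous", trait_label="toy"):
    """Build an AssociationTable from partial row dicts, filling defaults."""
    full = []
    for i, row in enumerate(rows):
        rec = dict(ROW_DEFAULTS, variant_id=f"rs{i}", **row)
        full.append(rec)
    return AssociationTable(pd.DataFrame(full), trait_label=trait_label, trait_type=trait_type)


def make_instruments(
    beta_exp,
    beta_out,
    se_out,
    se_exp=None,
    eaf_exp=None,
    eaf_out=None,
    n_exp=40_000,
    n_out=175_000,
):
    """Build a harmonized-instrument frame from effect arrays."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    k = len(beta_exp)
    se_exp = np.full(k, 0.01) if se_exp is None else np.asarray(se_exp, dtype=float)
    eaf_exp = np.full(k, 0.3) if eaf_exp is None else np.asarray(eaf_exp, dtype=float)
    eaf_out = eaf_exp.copy() if eaf_out is None else np.asarray(eaf_out, dtype=float)
    with np.errstate(divide="ignore"):
        wald_ratio = beta_out / beta_exp
        wald_se = se_out / np.abs(beta_exp)
    return pd.DataFrame(
        {
            "variant_id": [f"rs{i}" for i in range(k)],
            "chromosome": "1",
            "position": np.arange(k) * 20_000_000 + 1,
            "effect_allele": "A",
            "other_allele": "G",
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "eaf_exp": eaf_exp,
            "n_exp": float(n_exp),
            "beta_out": beta_out,
            "se_out": se_out,
            "eaf_out": eaf_out,
            "n_out": float(n_out),
            "wald_ratio": wald_ratio,
            "wald_se": wald_se,
        }
    )


@pytest.fixture(scope="session")
def table1():
    from mrcausal.simulate import table1_fixture

    return table1_fixture()


@pytest.fixture
def two_snp_instruments():
    """The hand-computed two-variant IVW fixture: ratios 0.5 and 1.0, se 0.1."""
    return make_instruments([1.0, 1.0], [0.5, 1.0], [0.1, 0.1])
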