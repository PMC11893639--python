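import numpy as np
import pandas as pd
import pytest

from ranklap.gwas_io import GwasSummary, PairedSnpTable


def make_summary(label, snp_ids, chroms, positions, pvalues, odds_ratios=None):
    n = len(snp_ids)
    return GwasSummary(
        study_label=label,
        df=pd.DataFrame(
            {
                "snp_id": list(snp_ids),
                "chrom": [str(c) for c in chroms],
                "pos": list(positions),
                "pvalue": list(pvalues),
                "odds_ratio": list(odds_ratios) if odds_ratios is not None else np.nan,
            }
        ),
    )


@pytest.fixture
def paired_table():
    """Small intersected table with distinct p-values on one chromosome."""
    rng = np.random.default_rng(7)
    n = 60
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i:03d}" for i in range(n)],
            "chrom": ["1"] * n,
            "pos": np.arange(1, n + 1) * 100,
            "pvalue_a": rng.random(n),
            "pvalue_b": rng.random(n),
        }
    )
    return PairedSnpTable(df=df)


@pytest.fixture
def toy_gwas_file(tmp_path):
    """Five-row tab-delimited summary file with nonstandard column names."""
    path = tmp_path / "toy.tsv"
    path.write_text(
        "MarkerName\tCHR\tBP\tP\tOR\n"
        + "".join(
            f"rs{i}\t{c}\t{p}\t{pv}\t{orr}\n"
            for i, c, p, pv, orr in [
                (1, 1, 100, 0.5, 1.2),
                (2, 2, 200, 0.001, 0.9),
                (3, "X", 300, 0.9, 1.5),
                (4, 22, 400, 1.0, 1.1),
                (5, 1, 500, 1e-8, 2.0),
            ]
        )
    )
    return path


TOY_COLUMN_MAP = {
    "snp_id": "MarkerName",
    "chrom": "CHR",
    "pos": "BP",
    "pvalue": "P",
    "odds_ratio": "OR",
}
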