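import pytest
from hypothesis import settings

from patternmap import DiscretizationRule, ExpressionProfile

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")


@pytest.fixture
def rule():
    return DiscretizationRule()  # log2 threshold 1.0 (two-fold), p < 0.05


@pytest.fixture
def fc_only_rule():
    return DiscretizationRule(p_threshold=None)


def make_profile(gene_id, fc, pvalue=None, **kw):
    """Profile from log2 fold changes; pvalue=None means FC-only input."""
    return ExpressionProfile(
        gene_id=gene_id,
        fc=tuple(float(v) for v in fc),
        pvalue=tuple(pvalue) if pvalue is not None else None,
        **kw,
    )


@pytest.fixture
def cohort_file(tmp_path):
    """Write a small tab-delimited cohort table and return its path."""

    def _write(rows, header="ID\tSymbol\tP_T1\tFC_T1\tP_T2\tFC_T2", name="cohort.tsv"):
        path = tmp_path / name
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    return _write
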