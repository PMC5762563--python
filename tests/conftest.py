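import numpy as np
import pytest

from comod.io import ExpressionMatrix


def make_expr(values, condition="c1", kind="log2_fpkm", classes=None,
              gene_ids=None, sample_ids=None):
    """Small ExpressionMatrix builder for tests (values: samples x genes)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ExpressionMatrix(
        condition_name=condition,
        gene_ids=gene_ids or [f"G{j}" for j in range(p)],
        sample_ids=sample_ids or [f"{condition}_s{i}" for i in range(n)],
        values=values,
        value_kind=kind,
        sample_class=classes,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_spd():
    """Factory for random symmetric positive-definite matrices."""

    def _make(p, seed=0, cond_floor=0.1):
        r = np.random.default_rng(seed)
        A = r.normal(size=(p + 3, p))
        return A.T @ A + cond_floor * np.eye(p)

    return _make
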