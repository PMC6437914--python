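import numpy as np
import pytest

from confects.model import ConfectModel
from confects.moderation import GeneStats


def random_gene_stats(rng, n, *, df=(3.0, 40.0), se=(0.05, 2.0), effect_scale=2.0):
    """Random but well-formed per-gene statistics for property tests."""
    return GeneStats(
        np.array([f"g{i}" for i in range(n)], dtype=object),
        rng.normal(0.0, effect_scale, n),
        rng.uniform(*se, n),
        rng.uniform(*df, n),
    )


class StepPValueModel(ConfectModel):
    """ConfectModel with explicit step-function p-values per gene.

    Gene i has p-value ``p_in[i]`` for thresholds up to ``drop_at[i]``
    (inclusive) and ``p_out[i]`` beyond — a monotone step function that
    lets tests realise an exact nested-set membership pattern.
    """

    def __init__(self, drop_at, p_in, p_out, signs=None):
        n = len(drop_at)
        self.drop_at = np.asarray(drop_at, dtype=float)
        self.p_in = np.asarray(p_in, dtype=float)
        self.p_out = np.asarray(p_out, dtype=float)
        effect = np.ones(n) if signs is None else np.asarray(signs, dtype=float)
        super().__init__(
            GeneStats(
                np.array([f"g{i + 1}" for i in range(n)], dtype=object),
                effect,
                np.ones(n),
                10.0,
            )
        )

    def pvalues(self, e, idx=None):
        if idx is None:
            idx = np.arange(len(self.drop_at))
        return np.where(e <= self.drop_at[idx] + 1e-12,
                        self.p_in[idx], self.p_out[idx])


@pytest.fixture
def nested_sets_model():
    """Nine genes realising the nested selections |S(0)| = 7, |S(0.5)| = 6,
    |S(1)| = 3, |S(1.5)| = 1, |S(2)| = 0 on a grid of step 0.5 at q = 0.05,
    so the confect magnitudes come out 1.5, 1, 1, 0.5, 0.5, 0.5, 0 with the
    last two genes unvalued.  Gene 3 is down-regulated to exercise signing.
    """
    drop_at = [1.5, 1.0, 1.0, 0.5, 0.5, 0.5, 0.0, -1.0, -1.0]
    p_in = [0.001] * 7 + [1.0, 1.0]
    p_out = [1.0] * 7 + [0.2, 0.3]
    signs = [1, 1, -1, 1, 1, 1, 1, 1, 1]
    return StepPValueModel(drop_at, p_in, p_out, signs=signs)
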