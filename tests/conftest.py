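import numpy as np
import pytest

from dicersite.pattern_engine import (
    CleavagePattern,
    CleavageSite,
    PatternConfig,
    PatternDataset,
    PreMiRNA,
)


@pytest.fixture
def two_site_hairpin():
    """An 80-nt hairpin with cleavage sites at intervals 27 and 49,
    mimicking the geometry of hsa-let-7a-1 (5p mature 6-27, 3p 50-71)."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGU"), size=80))
    struct = "(" * 33 + "." * 14 + ")" * 33
    return PreMiRNA("fix80", seq, struct,
                    sites=[CleavageSite(27, "5p"), CleavageSite(49, "3p")])


def make_dataset(labels, premirna_ids=None, s=14, seed=0):
    """Build a small PatternDataset with given labels (window content is
    arbitrary but consistent)."""
    rng = np.random.default_rng(seed)
    n = len(labels)
    if premirna_ids is None:
        premirna_ids = [f"h{i % 3}" for i in range(n)]
    context = {}
    samples = []
    for i, (lbl, pid) in enumerate(zip(labels, premirna_ids)):
        if pid not in context:
            seq = "".join(rng.choice(list("ACGU"), size=60))
            context[pid] = (seq, "(" * 25 + "." * 10 + ")" * 25)
        a = 1 + (i % 40)
        seq, struct = context[pid]
        samples.append(CleavagePattern(pid, a, seq[a - 1:a + s - 1],
                                       struct[a - 1:a + s - 1], int(lbl)))
    return PatternDataset(config=PatternConfig(s=s), samples=samples,
                          context=context)


@pytest.fixture
def tiny_dataset():
    return make_dataset([0, 3, 7, 0, 1, 13, 0, 5, 2, 9])
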