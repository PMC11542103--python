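import numpy as np
import pytest

from retvasc.synthetic import TreeParams, generate_tree


@pytest.fixture(scope="session")
def tree3():
    """Standard depth-3 synthetic image pair with truth (seed fixed)."""
    return generate_tree(TreeParams(depth=3, seed=1))


@pytest.fixture(scope="session")
def tree3_idps(tree3):
    from retvasc.phenotypes import compute_idps
    artery, vein, od, _ = tree3
    return compute_idps(artery, vein, od)
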