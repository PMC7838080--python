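import numpy as np
import pytest

import bahdscope as bs
from bahdscope.structure_pocket import ChargeModel, PocketPosition, _profile_from_positions


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_two_class_bundle(seed: int, substitution_rate: float = 0.1, members: int = 6):
    """Two planted families on charged-pocket scaffolds plus held-out queries.

    Family A carries an acidic pocket (net -3), family B a basic pocket
    (net +3); pocket sites are protected during evolution.  Returns
    (bundle, queries, truth verdicts).
    """
    rng = np.random.default_rng(seed)
    acid = [(100, "D"), (110, "E"), (120, "D"), (200, "S"), (210, "T")]
    base = [(100, "R"), (110, "K"), (120, "R"), (200, "S"), (210, "T")]
    sites = [p for p, _ in acid]
    sA = bs.make_scaffold_with_pocket(acid, 450, rng, "famA")
    sB = bs.make_scaffold_with_pocket(base, 450, rng, "famB")
    famA = bs.evolve_family(sA, members, substitution_rate, rng=rng, extra_protected=sites)
    famB = bs.evolve_family(sB, members, substitution_rate, rng=rng, extra_protected=sites)
    n_ref = members - 2
    refs = famA[:n_ref] + famB[:n_ref]
    labels = {r.id: bs.VERDICT_AMINE for r in famA[:n_ref]}
    labels |= {r.id: bs.VERDICT_SHIKIMATE for r in famB[:n_ref]}
    model = ChargeModel()
    profA = _profile_from_positions([PocketPosition(p, a) for p, a in acid], model)
    profB = _profile_from_positions([PocketPosition(p, a) for p, a in base], model)
    bundle = bs.ReferenceBundle(
        refs, labels, [bs.TemplateEntry(sA, profA), bs.TemplateEntry(sB, profB)]
    )
    queries = famA[n_ref:] + famB[n_ref:]
    truth = {q.id: bs.VERDICT_AMINE for q in famA[n_ref:]}
    truth |= {q.id: bs.VERDICT_SHIKIMATE for q in famB[n_ref:]}
    return bundle, queries, truth


@pytest.fixture
def two_class_bundle():
    return make_two_class_bundle(7)
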