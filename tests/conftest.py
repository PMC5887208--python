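import numpy as np
import pytest

from adescreen import SimConfig, StratumDefinition, generate
from adescreen.synthetic_data import InjectedEffect


def random_sim_config(seed, n_reports=None, n_drugs=None, n_events=None,
                      n_hists=2, inject=True):
    """A small random-but-reproducible simulation config for fixtures."""
    rng = np.random.default_rng([seed, 7])
    n_reports = n_reports or int(rng.integers(100, 500))
    n_drugs = n_drugs or int(rng.integers(3, 8))
    n_events = n_events or int(rng.integers(3, 8))
    drug_catalog = {f"D{i}": float(p) for i, p in
                    enumerate(rng.uniform(0.02, 0.3, n_drugs))}
    hist_catalog = {f"H{i}": float(p) for i, p in
                    enumerate(rng.uniform(0.2, 0.6, n_hists))}
    event_catalog = {f"E{i}": float(p) for i, p in
                     enumerate(rng.uniform(0.02, 0.15, n_events))}
    injected = []
    if inject:
        for _ in range(int(rng.integers(1, 4))):
            d = str(rng.choice(list(drug_catalog)))
            h = str(rng.choice(list(hist_catalog)))
            e = str(rng.choice(list(event_catalog)))
            rho = float(rng.uniform(1.0, 1.0 / event_catalog[e]))
            injected.append(InjectedEffect(d, h, e, rho))
    return SimConfig(n_reports=n_reports, drug_catalog=drug_catalog,
                     hist_catalog=hist_catalog, event_catalog=event_catalog,
                     injected_effects=injected, seed=seed)


def random_dataset(seed, **kwargs):
    cfg = random_sim_config(seed, **kwargs)
    dataset, _ = generate(cfg)
    strata = [StratumDefinition(name, frozenset(terms))
              for name, terms in cfg.strata.items()]
    return dataset, strata


@pytest.fixture
def small_dataset():
    return random_dataset(11)
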