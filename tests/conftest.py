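import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dera.network import Effect, Regulation, RegulatoryNetwork

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_network() -> RegulatoryNetwork:
    """A -> B (activation), B -| C (inhibition), D -> E (activation)."""
    return RegulatoryNetwork(frozenset({
        Regulation("A", "B", Effect.ACTIVATION),
        Regulation("B", "C", Effect.INHIBITION),
        Regulation("D", "E", Effect.ACTIVATION),
    }))


def random_network(rng: np.random.Generator, n_genes: int, n_edges: int,
                   inhibition_fraction: float = 0.4) -> RegulatoryNetwork:
    genes = [f"g{i}" for i in range(n_genes)]
    pairs = rng.choice(n_genes * (n_genes - 1), size=n_edges, replace=False)
    regs = set()
    for k in pairs:
        i, j = divmod(int(k), n_genes - 1)
        if j >= i:
            j += 1
        eff = Effect.INHIBITION if rng.random() < inhibition_fraction else Effect.ACTIVATION
        regs.add(Regulation(genes[i], genes[j], eff))
    return RegulatoryNetwork(frozenset(regs))


def random_indicator(rng: np.random.Generator, genes, n_samples: int,
                     p_nonzero: float = 0.4) -> pd.DataFrame:
    vals = rng.choice([-1, 0, 1], size=(len(genes), n_samples),
                      p=[p_nonzero / 2, 1 - p_nonzero, p_nonzero / 2])
    return pd.DataFrame(vals.astype(np.int8), index=list(genes),
                        columns=[f"s{j}" for j in range(n_samples)])
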