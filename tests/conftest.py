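import numpy as np
import pytest

import ffgraph as fg


@pytest.fixture
def registry():
    return fg.default_registry()


def build_eq4():
    """The four-variable, five-factor example graph:
    p(s1..s4) = fa(s1) fb(s1,s2,s3) fc(s2,s4) fd(s3) fe(s4)."""
    g = fg.FactorGraph("eq4")
    c = g.context_root
    s = {k: g.add_variable(c, f"s{k}") for k in (1, 2, 3, 4)}
    f = {
        "fa": g.add_factor(c, "fa", {"i": s[1]}),
        "fb": g.add_factor(c, "fb", {"i": s[1], "j": s[2], "k": s[3]}),
        "fc": g.add_factor(c, "fc", {"i": s[2], "j": s[4]}),
        "fd": g.add_factor(c, "fd", {"i": s[3]}),
        "fe": g.add_factor(c, "fe", {"i": s[4]}),
    }
    return g, s, f


@pytest.fixture
def eq4():
    return build_eq4()


def eq4_tables(graph, rng, domain_size=2):
    """Random positive tables for the eq4 structure."""
    domains = {v: list(range(domain_size)) for v in graph.variables}
    tables = {}
    for fid, fac in graph.factors.items():
        shape = tuple(domain_size for _ in fac.interfaces)
        tables[fid] = rng.uniform(0.1, 1.0, size=shape)
    return fg.TableSet(domains=domains, tables=tables)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
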