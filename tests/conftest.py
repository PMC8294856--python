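import datetime as dt
import io

import numpy as np
import pytest

from graphgo import pipeline
from graphgo.ontology import AnnotationRecord, load_obo
from graphgo.synthetic import SynthConfig, generate_benchmark

#: small single-domain chain/diamond ontology:
#:   root <- a <- b <- c   and   root <- d;  e has parents {a, d} (diamond)
CHAIN_OBO = """format-version: 1.2

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0000001
name: a
namespace: biological_process
is_a: GO:0008150 ! root

[Term]
id: GO:0000002
name: b
namespace: biological_process
is_a: GO:0000001 ! a

[Term]
id: GO:0000003
name: c
namespace: biological_process
is_a: GO:0000002 ! b

[Term]
id: GO:0000004
name: d
namespace: biological_process
is_a: GO:0008150 ! root

[Term]
id: GO:0000005
name: e
namespace: biological_process
is_a: GO:0000001 ! a
is_a: GO:0000004 ! d

[Term]
id: GO:0000006
name: gone
namespace: biological_process
is_a: GO:0000001 ! a
is_obsolete: true
"""

#: three-domain ontology, one child per domain
MULTI_DOMAIN_OBO = """format-version: 1.2

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0003674
name: molecular_function
namespace: molecular_function

[Term]
id: GO:0005575
name: cellular_component
namespace: cellular_component

[Term]
id: GO:0000010
name: bp child
namespace: biological_process
is_a: GO:0008150 ! root

[Term]
id: GO:0000020
name: mf child
namespace: molecular_function
is_a: GO:0003674 ! root

[Term]
id: GO:0000030
name: cc child
namespace: cellular_component
is_a: GO:0005575 ! root
"""


@pytest.fixture(scope="session")
def chain_ontology():
    return load_obo(io.StringIO(CHAIN_OBO))


@pytest.fixture(scope="session")
def multi_domain_ontology():
    return load_obo(io.StringIO(MULTI_DOMAIN_OBO))


def record(protein, term, evidence="IDA", date="2017-06-01"):
    return AnnotationRecord(protein, term, evidence, dt.date.fromisoformat(date))


@pytest.fixture(scope="session")
def small_benchmark():
    """Desk-scale synthetic benchmark shared by integration-level tests."""
    return generate_benchmark(SynthConfig(n_proteins=120, n_terms=30,
                                          n_signatures=60, seed=11))


@pytest.fixture(scope="session")
def small_dataset(small_benchmark):
    return pipeline.dataset_from_benchmark(small_benchmark)


def random_scores_truth(rng, n, k, quantized=False):
    """A random score matrix and a truth matrix with at least one positive."""
    s = rng.integers(0, 101, size=(n, k)) / 100 if quantized else rng.random((n, k))
    y = rng.random((n, k)) < 0.35
    while not y.any(axis=1).all():
        y[~y.any(axis=1)] = rng.random((int((~y.any(axis=1)).sum()), k)) < 0.5
    return np.asarray(s, dtype=float), y
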