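import pytest

from phosphopetri.netmodel import (
    DE_PHOSPHORYLATION,
    KINASE,
    PHOSPHATASE,
    PHOSPHORYLATION,
    SUBSTRATE_ONLY,
    WITH_PHOSPHORYLATION,
    WITHOUT_PHOSPHORYLATION,
    Interaction,
    PhosphoNetwork,
    ProteinNode,
)


def build_network(nodes, interactions):
    net = PhosphoNetwork(
        {n.id: n for n in nodes},
        list(interactions),
    )
    net.validate()
    return net


@pytest.fixture
def tiny_network():
    """Four proteins, three typed edges: two kinase edges and one
    phosphatase edge, with one without-phosphorylation enzyme."""
    return build_network(
        [
            ProteinNode("K1", KINASE, WITH_PHOSPHORYLATION),
            ProteinNode("K2", KINASE, WITHOUT_PHOSPHORYLATION),
            ProteinNode("F1", PHOSPHATASE, WITH_PHOSPHORYLATION),
            ProteinNode("S1", SUBSTRATE_ONLY),
        ],
        [
            Interaction("K1", "S1", PHOSPHORYLATION),
            Interaction("K2", "K1", PHOSPHORYLATION),
            Interaction("F1", "S1", DE_PHOSPHORYLATION),
        ],
    )


@pytest.fixture
def chain_network():
    """stimulus-target kinase K1 -> marker M (a 2-node chain)."""
    return build_network(
        [
            ProteinNode("K1", KINASE, WITH_PHOSPHORYLATION),
            ProteinNode("M", SUBSTRATE_ONLY),
        ],
        [Interaction("K1", "M", PHOSPHORYLATION)],
    )
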