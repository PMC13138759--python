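import numpy as np
import pytest

import vasodyn as v


@pytest.fixture(scope="session")
def default_network():
    return v.generate_default_network()


@pytest.fixture(scope="session")
def compiled(default_network):
    return v.CompiledNetwork(default_network)


@pytest.fixture(scope="session")
def small_config():
    """A small network (2 PAs, short pial fan) for fast solver checks."""
    return v.NetworkGenConfig(n_PA=2, segments_per_PA=5, n_pial_segments=4)


@pytest.fixture(scope="session")
def small_network(small_config):
    return v.generate_default_network(small_config)


def chain_network(n=3, diameter=16.0, length=30.0, abnp=90.0, vbnp=10.0):
    """A linear chain ABN - s0 - s1 - ... - VBN of equal segments."""
    net = v.VascularNetwork()
    net.add_node(v.NetworkNode("ABN", "artery_boundary", abnp))
    net.add_node(v.NetworkNode("VBN", "vein_boundary", vbnp))
    prev = "ABN"
    for i in range(n):
        nxt = "VBN" if i == n - 1 else f"n{i}"
        if nxt != "VBN":
            net.add_node(v.NetworkNode(nxt))
        net.add_segment(
            v.VesselSegment(
                id=f"s{i}",
                cls="PA",
                node_a=prev,
                node_b=nxt,
                length=length,
                diameter=diameter,
                d_active_max=diameter,
                wall_thickness=0.1 * diameter,
                cortical_depth=(i + 0.5) * length,
                contractility_index=1.0,
                is_arteriolar=True,
            )
        )
        prev = nxt
    return net
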