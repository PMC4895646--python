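"""Bundled example data."""

from __future__ import annotations

from importlib import resources

from .network import SignalingNetwork, _network_from_edge_list

__all__ = ["toy_network"]


def toy_network() -> SignalingNetwork:
    """A small synthetic growth-factor / stress signaling cascade.

    14 nodes and 15 signed, weighted edges with three receptor-like input
    nodes (EGFR, TNFR, DNADamage).  Illustrative only — the topology is
    hand-drawn for examples and tests, not a curated pathway map.
    """
    text = (
        resources.files("siglogic").joinpath("data/toy_network.tsv").read_text()
    )
    return _network_from_edge_list(text, "toy_network.tsv")
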