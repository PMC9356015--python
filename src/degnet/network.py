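"""DEG-interacted network construction and GO functional-module extraction.

The DEG-interacted network is the subgraph of the protein-interaction
network (PIN) induced on the DEGs together with their first interaction
neighbors.  A functional module is that network restricted to the genes
sharing one GO biological-process annotation; a module is retained only if
it contains at least one DEG and at least one interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EXPERIMENTAL_EVIDENCE_CODES",
    "KNOWN_EVIDENCE_CODES",
    "FunctionalModule",
    "build_deg_network",
    "filter_experimental_annotations",
    "extract_functional_modules",
]

# The GO consortium's experimental evidence branch.
EXPERIMENTAL_EVIDENCE_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})

KNOWN_EVIDENCE_CODES = EXPERIMENTAL_EVIDENCE_CODES | frozenset({
    "HTP", "HDA", "HMP", "HGI", "HEP",
    "IBA", "IBD", "IKR", "IRD",
    "ISS", "ISO", "ISA", "ISM", "IGC", "RCA",
    "TAS", "NAS", "IC", "ND", "IEA",
})

BIOLOGICAL_PROCESS = "P"


@dataclass(frozen=True)
class FunctionalModule:
    """One GO BP term's subnetwork of the DEG-interacted network."""

    term_id: str
    genes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    deg_members: frozenset[str]

    def validate(self) -> None:
        if not self.deg_members:
            raise ValueError(f"{self.term_id}: a module must contain at least one DEG")
        if not self.edges:
            raise ValueError(f"{self.term_id}: a module must contain at least one interaction")
        if not self.deg_members <= self.genes:
            raise ValueError(f"{self.term_id}: deg_members must be a subset of genes")
        for a, b in self.edges:
            if a not in self.genes or b not in self.genes:
                raise ValueError(f"{self.term_id}: edge ({a},{b}) leaves the module")


def _canonical_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def build_deg_network(degs: Iterable[str], pin: nx.Graph) -> nx.Graph:
    """Subgraph of the PIN induced on DEGs plus their first neighbors.

    DEGs absent from the PIN are logged and dropped.  DEGs of degree zero
    remain as isolated nodes (they can never satisfy the module edge rule
    on their own).
    """
    degs = set(degs)
    present = degs & set(pin.nodes)
    missing = degs - present
    if missing:
        logger.warning("build_deg_network: %d DEGs absent from the PIN", len(missing))
    nodes = set(present)
    for d in present:
        nodes.update(pin.neighbors(d))
    return nx.Graph(pin.subgraph(nodes))


def filter_experimental_annotations(
    annotations: pd.DataFrame,
    evidence_codes: frozenset[str] = EXPERIMENTAL_EVIDENCE_CODES,
    aspect: str = BIOLOGICAL_PROCESS,
) -> pd.DataFrame:
    """Keep biological-process annotations supported by experimental evidence.

    Expects columns ``gene``, ``term``, ``evidence``, ``aspect``.  Rows with
    evidence codes outside the known GO vocabulary are dropped and logged.
    """
    unknown = ~annotations["evidence"].isin(KNOWN_EVIDENCE_CODES)
    if unknown.any():
        logger.warning(
            "filter_experimental_annotations: %d rows with unknown evidence codes dropped: %s",
            int(unknown.sum()),
            sorted(annotations.loc[unknown, "evidence"].unique())[:5],
        )
    keep = annotations["evidence"].isin(evidence_codes) & (annotations["aspect"] == aspect)
    return annotations.loc[keep & ~unknown].copy()


def extract_functional_modules(
    net: nx.Graph,
    annotations: pd.DataFrame,
    degs: Iterable[str],
) -> list[FunctionalModule]:
    """Extract per-GO-term functional modules from the DEG-interacted network.

    For each term, the module genes are the annotated genes present in the
    network and the module edges are the network edges induced on them.
    Modules lacking a DEG member or an interaction are discarded.  The
    result is sorted by term id and independent of annotation or edge order.
    """
    degs = set(degs)
    nodes = set(net.nodes)
    modules: list[FunctionalModule] = []
    for term, rows in annotations.groupby("term", sort=True):
        genes = set(rows["gene"]) & nodes
        if len(genes) < 2:
            continue
        sub = net.subgraph(genes)
        edges = frozenset(_canonical_edge(a, b) for a, b in sub.edges)
        deg_members = frozenset(genes & degs)
        if not edges or not deg_members:
            continue
        module = FunctionalModule(
            term_id=str(term),
            genes=frozenset(genes),
            edges=edges,
            deg_members=deg_members,
        )
        module.validate()
        modules.append(module)
    logger.info("extract_functional_modules: %d modules retained", len(modules))
    return modules
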