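"""Fatty-acid pathway model and pathway distances for brutto-annotated lipids.

Targeted lipidomics panels report *brutto* compositions only: the summed
side-chain carbon count and double-bond count (e.g. ``PC aa C38:4``), without
positional information.  To relate a pair of measured lipids to the fatty
acid biosynthesis network, every combinatorial decomposition of the brutto
composition into concrete fatty-acid residues is enumerated, each residue
pair is scored by its shortest path on the curated reaction graph
(elongation = +/-C2, desaturation = +/-1 double bond, beta-oxidation = -C2),
and the minimum total number of reaction steps over all decompositions is
the pathway distance.  Fatty acids of identical mass from different pathways
(e.g. omega-3 and omega-6 C20:4) are merged into a single node.  Unconnected
pairs get a formal distance of infinity; reversibility is ignored, so
distances are symmetric.

Acyl-carnitines live on a separate beta-oxidation chain of C2 degradation
steps (C10 -> C8 -> C6 ...); distances across projection domains (carnitine
vs. biosynthesis lipid, or non-lipid classes) are not applicable.
"""

from __future__ import annotations

import importlib.resources
import math
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LipidAnnotation",
    "FattyAcid",
    "PathwayModel",
    "ParseError",
    "parse_metabolite_name",
    "default_model_path",
    "load_pathway_model",
    "write_pathway_model",
    "enumerate_sidechain_variants",
    "fatty_acid_distance",
    "metabolite_pathway_distance",
    "distance_matrix",
    "AMINO_ACIDS",
    "BIOSYNTHESIS_CLASSES",
]

AMINO_ACIDS = {
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "xLeu", "Lys", "Met", "Orn", "Phe", "Pro", "Ser", "Thr", "Trp",
    "Tyr", "Val",
}

# classes projected onto the fatty-acid biosynthesis graph
BIOSYNTHESIS_CLASSES = {
    "diacyl-PC",
    "acyl-alkyl-PC",
    "lyso-PC",
    "sphingomyelin",
    "hydroxy-sphingomyelin",
}


class ParseError(ValueError):
    """Metabolite id does not follow the panel nomenclature."""


@dataclass(frozen=True)
class LipidAnnotation:
    """Parsed panel metabolite: class, brutto composition, residue count."""

    metabolite_id: str
    metabolite_class: str
    total_carbons: int | None = None
    total_double_bonds: int | None = None
    residue_count: int | None = None
    variant: str | None = None  # carnitine OH / DC / M-DC modifications

    @property
    def projection_domain(self) -> str | None:
        """"biosynthesis", "beta_oxidation", or None for unprojectable classes."""
        if self.metabolite_class in BIOSYNTHESIS_CLASSES:
            return "biosynthesis"
        if self.metabolite_class == "acyl-carnitine" and self.variant is None:
            return "beta_oxidation"
        return None


_PATTERNS: list[tuple[re.Pattern, str, int]] = [
    (re.compile(r"^PC aa C(\d+):(\d+)$"), "diacyl-PC", 2),
    (re.compile(r"^PC ae C(\d+):(\d+)$"), "acyl-alkyl-PC", 2),
    (re.compile(r"^lysoPC a C(\d+):(\d+)$"), "lyso-PC", 1),
    (re.compile(r"^SM \(OH\) C(\d+):(\d+)$"), "hydroxy-sphingomyelin", 1),
    (re.compile(r"^SM C(\d+):(\d+)-OH$"), "hydroxy-sphingomyelin", 1),
    (re.compile(r"^SM C(\d+):(\d+)$"), "sphingomyelin", 1),
]
_CARN = re.compile(r"^C(\d+):(\d+)(?:-(OH|DC|M-DC))?-carn$")


def parse_metabolite_name(metabolite_id: str) -> LipidAnnotation:
    """Deterministically parse a panel metabolite id.

    Recognizes diacyl/acyl-alkyl/lyso phosphatidylcholines, (hydroxy-)
    sphingomyelins, acyl-carnitines with OH/DC/M-DC variants, amino acids,
    and the hexose.  Raises :class:`ParseError` otherwise.
    """
    mid = metabolite_id.strip()
    if not mid:
        raise ParseError("empty metabolite id")
    if mid in AMINO_ACIDS:
        return LipidAnnotation(mid, "amino acid")
    if mid in ("H1", "Hexose", "hexose"):
        return LipidAnnotation(mid, "hexose")
    m = _CARN.match(mid)
    if m:
        return LipidAnnotation(
            mid,
            "acyl-carnitine",
            total_carbons=int(m.group(1)),
            total_double_bonds=int(m.group(2)),
            residue_count=1,
            variant=m.group(3),
        )
    for pat, cls, residues in _PATTERNS:
        m = pat.match(mid)
        if m:
            return LipidAnnotation(
                mid,
                cls,
                total_carbons=int(m.group(1)),
                total_double_bonds=int(m.group(2)),
                residue_count=residues,
            )
    raise ParseError(f"cannot parse metabolite id {mid!r}")


@dataclass(frozen=True)
class FattyAcid:
    """A fatty-acid species identified by carbon and double-bond counts."""

    carbons: int
    double_bonds: int
    tags: frozenset[str] = field(default_factory=frozenset)

    def __str__(self) -> str:
        return f"C{self.carbons}:{self.double_bonds}"


def _fa_key(carbons: int, double_bonds: int) -> tuple[int, int]:
    return (int(carbons), int(double_bonds))


class PathwayModel:
    """Curated fatty-acid reaction graph plus a beta-oxidation chain.

    ``biosynthesis`` and ``beta_oxidation`` are undirected simple graphs over
    ``(carbons, double_bonds)`` node keys; node ``tags`` record pathway
    membership (de-novo, omega-3, omega-6; merged isobaric species keep all
    source tags).
    """

    def __init__(
        self,
        biosynthesis: nx.Graph,
        beta_oxidation: nx.Graph,
    ):
        self.biosynthesis = biosynthesis
        self.beta_oxidation = beta_oxidation
        for g in (biosynthesis, beta_oxidation):
            for (c, d) in g.nodes:
                if c < 2 or c % 2 != 0:
                    raise ValueError(f"fatty acid C{c}:{d} has an odd/too-small carbon count")
                if d < 0:
                    raise ValueError("negative double-bond count")

    def graph(self, domain: str) -> nx.Graph:
        if domain == "biosynthesis":
            return self.biosynthesis
        if domain == "beta_oxidation":
            return self.beta_oxidation
        raise KeyError(f"unknown projection domain {domain!r}")

    def fatty_acids(self, domain: str = "biosynthesis") -> list[FattyAcid]:
        g = self.graph(domain)
        return [
            FattyAcid(c, d, frozenset(g.nodes[(c, d)].get("tags", ())))
            for (c, d) in sorted(g.nodes)
        ]

    def has_fatty_acid(self, carbons: int, double_bonds: int, domain: str = "biosynthesis") -> bool:
        return _fa_key(carbons, double_bonds) in self.graph(domain)


def _build_graph(nodes: list[dict], edges: list[dict]) -> nx.Graph:
    g = nx.Graph()
    for nd in nodes:
        key = _fa_key(nd["carbons"], nd["double_bonds"])
        tags = set(nd.get("tags", []))
        if key in g:
            # isobaric merge: same mass from different pathways -> one node
            g.nodes[key]["tags"] = tuple(sorted(set(g.nodes[key]["tags"]) | tags))
        else:
            g.add_node(key, tags=tuple(sorted(tags)))
    for ed in edges:
        a = _fa_key(*ed["from"])
        b = _fa_key(*ed["to"])
        for key in (a, b):
            if key not in g:
                raise ValueError(f"edge references undeclared fatty acid C{key[0]}:{key[1]}")
        if a == b:
            raise ValueError("self-loop reaction in pathway model")
        g.add_edge(a, b, reaction=ed.get("type", "unspecified"))
    return g


def load_pathway_model(path) -> PathwayModel:
    """Load a pathway model from its YAML description.

    The file lists fatty-acid nodes (carbons, double_bonds, tags) and edges
    (from, to, type) for the biosynthesis graph and the beta-oxidation chain.
    Nodes with identical composition are merged with their tags combined.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    bio = _build_graph(
        doc.get("biosynthesis", {}).get("fatty_acids", []),
        doc.get("biosynthesis", {}).get("reactions", []),
    )
    box = _build_graph(
        doc.get("beta_oxidation", {}).get("fatty_acids", []),
        doc.get("beta_oxidation", {}).get("reactions", []),
    )
    return PathwayModel(bio, box)


def write_pathway_model(model: PathwayModel, path) -> None:
    def dump(g: nx.Graph) -> dict:
        return {
            "fatty_acids": [
                {"carbons": c, "double_bonds": d, "tags": list(g.nodes[(c, d)].get("tags", ()))}
                for (c, d) in sorted(g.nodes)
            ],
            "reactions": [
                {"from": list(a), "to": list(b), "type": g.edges[a, b].get("reaction", "unspecified")}
                for a, b in sorted(g.edges)
            ],
        }

    doc = {"biosynthesis": dump(model.biosynthesis), "beta_oxidation": dump(model.beta_oxidation)}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_model_path():
    """Path of the bundled curated fatty-acid model."""
    return importlib.resources.files("ggmetab") / "data" / "fatty_acid_model.yaml"


def load_default_model() -> PathwayModel:
    return load_pathway_model(default_model_path())


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def fatty_acid_distance(
    fa1: tuple[int, int] | FattyAcid,
    fa2: tuple[int, int] | FattyAcid,
    model: PathwayModel,
    domain: str = "biosynthesis",
) -> float:
    """Shortest-path reaction-step count between two fatty acids.

    0 for identical species, ``inf`` if they lie in disjoint components.
    Unknown fatty acids raise a lookup error.
    """
    k1 = _fa_key(fa1.carbons, fa1.double_bonds) if isinstance(fa1, FattyAcid) else _fa_key(*fa1)
    k2 = _fa_key(fa2.carbons, fa2.double_bonds) if isinstance(fa2, FattyAcid) else _fa_key(*fa2)
    g = model.graph(domain)
    for k in (k1, k2):
        if k not in g:
            raise KeyError(f"fatty acid C{k[0]}:{k[1]} is not in the {domain} model")
    if k1 == k2:
        return 0.0
    try:
        return float(nx.shortest_path_length(g, k1, k2))
    except nx.NetworkXNoPath:
        return math.inf


def enumerate_sidechain_variants(
    annotation: LipidAnnotation, model: PathwayModel
) -> set[tuple[tuple[int, int], ...]]:
    """All decompositions of a brutto composition into model fatty acids.

    Single-residue lipids yield the single fatty acid (if present in the
    model); two-residue lipids yield every unordered pair of model fatty
    acids whose carbons and double bonds sum to the brutto totals.  An empty
    set means no decomposition exists.
    """
    if annotation.residue_count not in (1, 2):
        raise ValueError(f"{annotation.metabolite_id} is not a side-chain lipid")
    domain = annotation.projection_domain
    if domain is None:
        raise ValueError(f"{annotation.metabolite_id} does not project onto the model")
    tc, td = annotation.total_carbons, annotation.total_double_bonds
    if annotation.residue_count == 1:
        if model.has_fatty_acid(tc, td, domain):
            return {((tc, td),)}
        return set()
    fas = [(fa.carbons, fa.double_bonds) for fa in model.fatty_acids(domain)]
    out: set[tuple[tuple[int, int], ...]] = set()
    for c1, d1 in fas:
        c2, d2 = tc - c1, td - d1
        if (c2, d2) in set(fas):
            pair = tuple(sorted([(c1, d1), (c2, d2)]))
            out.add(pair)
    return out


def metabolite_pathway_distance(
    met1: str | LipidAnnotation, met2: str | LipidAnnotation, model: PathwayModel
) -> float:
    """Minimal reaction-step distance between two measured metabolites.

    Minimizes, over all side-chain decompositions of both metabolites and
    over the two ways of matching residues, the summed per-residue shortest
    path distances.  Returns ``inf`` when no finite combination exists and
    ``nan`` (not applicable) for unprojectable classes, cross-domain pairs,
    or pairs with differing residue counts.
    """
    a1 = parse_metabolite_name(met1) if isinstance(met1, str) else met1
    a2 = parse_metabolite_name(met2) if isinstance(met2, str) else met2
    if a1.metabolite_id == a2.metabolite_id:
        return 0.0
    d1, d2 = a1.projection_domain, a2.projection_domain
    if d1 is None or d2 is None or d1 != d2 or a1.residue_count != a2.residue_count:
        return math.nan
    v1 = enumerate_sidechain_variants(a1, model)
    v2 = enumerate_sidechain_variants(a2, model)
    best = math.inf
    for dec1 in v1:
        for dec2 in v2:
            if len(dec1) == 1:
                cand = fatty_acid_distance(dec1[0], dec2[0], model, d1)
                best = min(best, cand)
            else:
                (p, q), (r, s) = dec1, dec2
                straight = fatty_acid_distance(p, r, model, d1) + fatty_acid_distance(q, s, model, d1)
                crossed = fatty_acid_distance(p, s, model, d1) + fatty_acid_distance(q, r, model, d1)
                best = min(best, straight, crossed)
    return best


def distance_matrix(panel: list[str], model: PathwayModel) -> pd.DataFrame:
    """Pairwise pathway distances for a metabolite panel.

    Symmetric with zero diagonal; ``inf`` marks unconnected pairs within a
    projection domain, ``NaN`` marks not-applicable pairs (cross-domain or
    unprojectable classes).
    """
    annos = [parse_metabolite_name(mid) for mid in panel]
    k = len(panel)
    D = np.full((k, k), np.nan)
    np.fill_diagonal(D, 0.0)
    # BFS distances are cached per fatty-acid pair through networkx's
    # shortest_path_length; panel sizes are small enough for direct calls.
    for i in range(k):
        for j in range(i + 1, k):
            d = metabolite_pathway_distance(annos[i], annos[j], model)
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=panel, columns=panel)
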