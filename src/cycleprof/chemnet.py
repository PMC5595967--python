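"""Chemical-similarity networks over hit compounds from bit fingerprints.

Fingerprints (e.g. FP2 path-based bits) are supplied by the user, not
computed here; pairwise Tanimoto coefficients above a threshold become
weighted edges of an undirected compound network exported for Cytoscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from cycleprof.errors import ValidationError


@dataclass(frozen=True)
class BitFingerprint:
    compound: str
    bits: frozenset[int]
    nbits: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", frozenset(int(b) for b in self.bits))
        if any(not (0 <= b < self.nbits) for b in self.bits):
            raise ValidationError(
                f"{self.compound}: bit position outside [0, {self.nbits})"
            )


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """|A n B| / |A u B|; 0 by convention when both sets are empty."""
    if a.nbits != b.nbits:
        raise ValidationError(f"fingerprint lengths differ: {a.nbits} != {b.nbits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def similarity_network(fps: list[BitFingerprint], threshold: float = 0.5) -> nx.Graph:
    """Undirected simple graph: nodes all compounds (isolates kept), an edge
    wherever Tanimoto similarity >= threshold, weighted by the similarity."""
    if len(fps) < 2:
        raise ValidationError("need >= 2 fingerprints")
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError(f"threshold must be in [0, 1], got {threshold}")
    g = nx.Graph()
    g.add_nodes_from(fp.compound for fp in fps)
    for i, a in enumerate(fps):
        for b in fps[i + 1:]:
            sim = tanimoto(a, b)
            if sim >= threshold:
                g.add_edge(a.compound, b.compound, weight=sim)
    return g


def read_bit_fingerprints(path) -> list[BitFingerprint]:
    """One compound per line: name, nbits, comma-separated bit positions."""
    fps = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 2:
                raise ValidationError(f"unparseable fingerprint line: {line!r}")
            name, nbits = parts[0], int(parts[1])
            bits = frozenset(int(p) for p in parts[2:] if p)
            fps.append(BitFingerprint(compound=name, bits=bits, nbits=nbits))
    return fps


def write_sif(g: nx.Graph, path) -> None:
    """Cytoscape SIF: 'a sim b' per edge, bare node line for isolates."""
    with open(path, "w") as fh:
        for a, b in sorted(g.edges()):
            fh.write(f"{a}\tsim\t{b}\n")
        for node in sorted(nx.isolates(g)):
            fh.write(f"{node}\n")
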