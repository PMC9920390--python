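"""Deterministic synthetic fixture knowledge base.

Stands in for a large assigned-spectrum collection so every module is
testable offline.  Molecules come from a programmatically enumerated set of
small organic structures over {C, H, N, O, S} (substituted benzenes plus
chains and heterocycles); each carbon receives a deterministic pseudo-shift:
a coarse chemical window chosen from its hybridization and hetero
neighbourhood, positioned within the window by a stable hash of its sphere-3
environment code.  Identical environments therefore always receive identical
shifts (so symmetry-equivalent carbons merge into one signal exactly), and
the same seed reproduces the same knowledge base byte for byte.  Optional
Gaussian jitter emulates experimental scatter for query spectra.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass

from .chem_model import MoleculeGraph, canonical_signature, hose_code, hybridization_of
from .knowledge_base import AssignedSpectrum, KbRecord, assign_equivalence, ingest_record

_SUBSTITUENTS = [
    "O",        # hydroxy
    "OC",       # methoxy
    "C",        # methyl
    "CC",       # ethyl
    "N",        # amino
    "NC(C)=O",  # acetamido
    "C(C)=O",   # acetyl
    "C(O)=O",   # carboxy
    "C=C",      # vinyl
    "CO",       # hydroxymethyl
    "SC",       # methylthio
    "C#N",      # cyano
]

_CHAINS_AND_RINGS = [
    # alcohols / ethers / amines
    "CO", "CCO", "CCCO", "CC(C)O", "CC(C)(C)O", "COC", "CCOCC", "CN", "CCN",
    "CCCN", "CNC", "CN(C)C", "OCCO", "OCCN", "CSC", "CCS", "CC(O)CO",
    # carbonyls
    "CC=O", "CCC=O", "CC(C)=O", "CCC(C)=O", "CC(=O)O", "CCC(=O)O",
    "CC(=O)OC", "CC(=O)OCC", "CC(=O)N", "CC(=O)NC", "CCC(=O)NC", "OCC(=O)O",
    "CC(=O)SC",
    # alkenes / alkynes / nitriles
    "C=C", "CC=C", "CC=CC", "C=CC=C", "CC#C", "CC#CC", "CC#N", "CCC#N",
    "C=CC(=O)OC", "C=CC(=O)OCC", "CC=CC(=O)OCC",
    # heterocycles (written kekulized on read)
    "c1ccoc1", "c1ccsc1", "c1cc[nH]c1", "c1ccncc1", "c1ccncn1", "c1cncnc1",
    "c1cocn1", "c1cscn1", "Cc1ccco1", "Cc1cccs1", "Cc1ccncc1",
    # benzylic / mixed
    "OCc1ccccc1", "NCc1ccccc1", "CC(O)c1ccccc1", "CC(=O)c1ccccc1",
    "C=Cc1ccccc1", "CCOC(=O)c1ccccc1", "CC(=O)Oc1ccccc1",
]


def _aromatic_smiles() -> list[str]:
    out = ["c1ccccc1"]
    for s in _SUBSTITUENTS:
        out.append(f"c1ccc({s})cc1")
    subs = list(_SUBSTITUENTS)
    for i, a in enumerate(subs):
        for b in subs[i:]:
            out.append(f"c1cc({a})ccc1{b}")        # para
            out.append(f"c1ccc({a})c({b})c1")      # ortho
    return out


def default_smiles_catalog() -> list[str]:
    return _aromatic_smiles() + _CHAINS_AND_RINGS


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 42
    jitter_sigma: float = 0.0
    smiles: tuple[str, ...] | None = None  # None = bundled catalog


def _stable_fraction(text: str) -> float:
    digest = hashlib.md5(text.encode()).hexdigest()
    return int(digest[:8], 16) / 0xFFFFFFFF


def _shift_window(graph: MoleculeGraph, i: int) -> tuple[float, float]:
    """Element-typical 13C window from hybridization and hetero neighbours."""
    hyb = hybridization_of(graph, i)
    nbr = [(graph.atoms[j].element, o) for j, o in graph.neighbors(i)]
    n_o = sum(1 for el, _ in nbr if el == "O")
    n_n = sum(1 for el, _ in nbr if el == "N")
    n_s = sum(1 for el, _ in nbr if el == "S")
    if hyb == "sp3":
        if n_o:
            return (50.0, 90.0)
        if n_n:
            return (25.0, 60.0)
        if n_s:
            return (10.0, 45.0)
        return (5.0, 45.0)
    if hyb == "sp2":
        double_o = any(el == "O" and o == 2 for el, o in nbr)
        if double_o:
            # carbonyl: esters/amides/acids sit lower than ketones/aldehydes
            if n_o > 1 or n_n:
                return (160.0, 178.0)
            return (185.0, 210.0)
        if n_o:
            return (145.0, 165.0)
        if n_n:
            return (135.0, 160.0)
        return (100.0, 145.0)
    # sp: alkynes low, nitriles higher
    if n_n and any(el == "N" and o == 3 for el, o in nbr):
        return (110.0, 125.0)
    return (65.0, 95.0)


def pseudo_shift(graph: MoleculeGraph, i: int) -> float:
    """Deterministic 13C pseudo-shift of carbon *i* (ppm, 2 decimals)."""
    lo, hi = _shift_window(graph, i)
    code = hose_code(graph, i, 3).text
    return round(lo + _stable_fraction(code) * (hi - lo), 2)


# A record is only kept when its spectrum cannot be mistaken for a
# sub-spectrum of another record: every dereplication query derived from the
# KB must have a unique best explanation.  The radius covers the worst-case
# query jitter plus a safety margin.
IDENTIFIABILITY_RADIUS = 0.8


def _spectrum_embeds(r: KbRecord, s: KbRecord, radius: float) -> bool:
    """True when every signal of *r* pairs with a distinct signal of *s*
    of equal multiplicity and equivalence within *radius* ppm."""
    import networkx as nx

    rs = r.spectrum.signals
    ss = s.spectrum.signals
    if len(rs) > len(ss):
        return False
    g = nx.Graph()
    left = []
    for i, a in enumerate(rs):
        node = ("r", i)
        left.append(node)
        for j, b in enumerate(ss):
            if a.multiplicity == b.multiplicity and a.equivalence == b.equivalence \
                    and abs(a.shift - b.shift) <= radius:
                g.add_edge(node, ("s", j))
    if any(node not in g for node in left):
        return False
    match = nx.algorithms.bipartite.maximum_matching(g, top_nodes=left)
    return sum(1 for k in match if k[0] == "r") == len(rs)


def make_fixture_kb(spec: FixtureSpec = FixtureSpec()) -> list[KbRecord]:
    """Build the synthetic knowledge base (>= 200 records, seed-stable).

    Besides validity, the KB guarantees spectral identifiability: a record
    whose full signal list embeds within ``IDENTIFIABILITY_RADIUS`` in
    another record's spectrum (same multiplicities and equivalences) is
    excluded, since no spectrum-only matcher could retrieve it uniquely.
    """
    smiles = list(spec.smiles) if spec.smiles is not None else default_smiles_catalog()
    graphs: dict[str, MoleculeGraph] = {}
    for s in smiles:
        g = MoleculeGraph.from_smiles(s)
        graphs.setdefault(canonical_signature(g), g)
    rng = random.Random(spec.seed)
    records = []
    for signature in sorted(graphs):
        graph = graphs[signature]
        shifts = {}
        for i in graph.carbons():
            value = pseudo_shift(graph, i)
            if spec.jitter_sigma > 0:
                value = round(value + rng.gauss(0.0, spec.jitter_sigma), 2)
            shifts[i] = value
        records.append(ingest_record(graph, shifts, identifier="pending"))
    kept = [
        r for r in records
        if not any(s is not r and _spectrum_embeds(r, s, IDENTIFIABILITY_RADIUS)
                   for s in records)
    ]
    return [
        KbRecord(molecule=r.molecule, spectrum=r.spectrum, identifier=f"FIX{n:04d}")
        for n, r in enumerate(kept, start=1)
    ]


def correlation_set_for(record: KbRecord):
    """Derive a complete synthetic correlation table from a known structure.

    Emulates what a spectroscopist would extract from clean 1D/2D spectra of
    the record's molecule: one 13C row per carbon (multiplicity from the
    attached protons), one proton group per protonated heavy atom, HSQC links
    for protonated carbons, HMBC correlations from every proton to all heavy
    carbons within two bonds, and COSY links between protons on adjacent
    carbons.  Shifts are the record's assigned values, so the table is
    consistent with the knowledge base the record came from.
    """
    from .structure_generation import CarbonSignal, CorrelationSet, ProtonGroup

    graph = record.molecule
    shifts = record.shift_map()
    carbons = graph.carbons()
    carbon_id = {c: f"C{k + 1}" for k, c in enumerate(carbons)}
    rows = tuple(
        CarbonSignal(id=carbon_id[c], shift=shifts[c],
                     multiplicity=graph.atoms[c].attached_h)
        for c in carbons
    )
    protons: list[ProtonGroup] = []
    hsqc: list[tuple[str, str]] = []
    hmbc: list[tuple[str, str]] = []
    cosy: list[tuple[str, str]] = []
    hetero: list[tuple[str, str]] = []
    host_of: dict[str, int] = {}
    hetero_seen: dict[str, int] = {}
    for i, atom in enumerate(graph.atoms):
        if atom.attached_h == 0:
            continue
        if atom.element == "C":
            pid = f"H{carbon_id[i][1:]}"
            hsqc.append((pid, carbon_id[i]))
        else:
            k = hetero_seen.get(atom.element, 0) + 1
            hetero_seen[atom.element] = k
            pid = f"H{atom.element}{k}"
            hetero.append((pid, atom.element))
        protons.append(ProtonGroup(id=pid, shift=0.0, integral=float(atom.attached_h)))
        host_of[pid] = i
        dist = graph.distances_from(i)
        for c in carbons:
            if c != i and 1 <= dist[c] <= 2:
                hmbc.append((pid, carbon_id[c]))
    hosts = {i: pid for pid, i in host_of.items()}
    for i, j, _ in graph.bonds:
        if i in hosts and j in hosts and graph.atoms[i].element == "C" \
                and graph.atoms[j].element == "C":
            cosy.append((hosts[i], hosts[j]))
    return CorrelationSet(
        carbons=rows, proton_groups=tuple(protons), hsqc=tuple(hsqc),
        hmbc=tuple(hmbc), cosy=tuple(cosy), hetero_attachments=tuple(hetero),
    )


def jittered_query(record: KbRecord, sigma: float, seed: int) -> AssignedSpectrum:
    """Query spectrum of a record with bounded uniform shift jitter.

    Jitter is drawn uniformly from [-sigma, sigma] per signal, so the
    deviation of a self-match is bounded by ``sigma`` by construction.
    """
    rng = random.Random(seed)
    entries = []
    for s in record.spectrum.signals:
        delta = rng.uniform(-sigma, sigma)
        for idx in s.atom_indices:
            entries.append((round(s.shift + delta, 3), s.multiplicity, idx))
    return AssignedSpectrum(signals=tuple(assign_equivalence(entries)))
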