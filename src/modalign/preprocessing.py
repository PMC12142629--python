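"""FASTA/PDB preprocessing: protein records, description text, residue
coordinates and atom graphs.

FASTA input is expected in the RCSB header dialect
``>1ABC_1|Chains A, B|molecule name|organism`` — one record per entity, with
the entity's chains listed in the second field.  Other dialects are rejected
loudly rather than guessed at.  PDB coordinate files are read with gemmi.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field

import gemmi
import numpy as np
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "ResidueCoordinateRecord",
    "AtomGraph",
    "parse_fasta",
    "count_chains",
    "render_description",
    "pdb_to_residue_records",
    "pdb_to_atom_graph",
    "pool_node_embeddings",
]

logger = logging.getLogger(__name__)

_HEADER_RE = re.compile(
    r"^(?P<pid>[A-Za-z0-9]{4})_(?P<entity>\d+)\|"
    r"Chains? (?P<chains>[A-Za-z0-9]+(?:,\s*[A-Za-z0-9]+)*)\|"
    r"(?P<molecule>[^|]+)\|"
    r"(?P<organism>[^|]+)$"
)

DESCRIPTION_TEMPLATE = (
    "The protein structure {pid} has a sequence length of {length} amino "
    "acids. Here is more information: The protein structure {pid} involves "
    "the following chains: {chains}. The protein is named {name} and is "
    "derived from the organism {organism}."
)


@dataclass
class ProteinRecord:
    """Merged view of all FASTA entity records sharing one protein ID."""

    protein_id: str
    chains: list[str]
    molecule_name: str
    organism: str
    sequences: dict[str, str] = field(default_factory=dict)  # chain -> AA string
    chain_organisms: dict[str, str] = field(default_factory=dict)

    @property
    def sequence_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def chain_multiplicity(self) -> str:
        return count_chains(self)


@dataclass
class ResidueCoordinateRecord:
    """Per-residue coordinates in the nested-list layout used by structure
    encoders: ``coords[i]`` is a list of [x, y, z] triples for residue i."""

    ID: str
    seq: str
    coords: list[list[list[float]]]

    def to_dict(self) -> dict:
        return {"ID": self.ID, "seq": self.seq, "coords": self.coords}


@dataclass
class AtomGraph:
    """Heavy-atom graph: nodes carry element and residue index, edges are
    undirected pairs below the bond cutoff."""

    elements: list[str]
    residue_index: list[int]
    edges: set[tuple[int, int]]     # stored with i < j

    @property
    def n_nodes(self) -> int:
        return len(self.elements)


class FastaParseError(ValueError):
    pass


def parse_fasta(text: str) -> list[ProteinRecord]:
    """Parse RCSB-dialect FASTA text into one record per protein ID.

    Entity records sharing an ID are merged; each chain listed on an entity
    contributes one copy of that entity's sequence to the total length.  The
    amino-acid sequence is retained on the record but never rendered into
    descriptions.
    """
    if ">" not in text:
        raise FastaParseError("no FASTA header found in input")
    records: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        header = rec.description
        m = _HEADER_RE.match(header)
        if m is None:
            raise FastaParseError(f"malformed RCSB FASTA header: {header!r}")
        pid = m.group("pid")
        chains = [c.strip() for c in m.group("chains").split(",")]
        molecule = m.group("molecule").strip()
        organism = m.group("organism").strip()
        pr = records.get(pid)
        if pr is None:
            pr = ProteinRecord(protein_id=pid, chains=[], molecule_name=molecule,
                               organism=organism)
            records[pid] = pr
        for c in chains:
            if c not in pr.chains:
                pr.chains.append(c)
            pr.sequences[c] = str(rec.seq)
            pr.chain_organisms[c] = organism
        # multichain entries may carry distinct per-chain organisms
        orgs = list(dict.fromkeys(pr.chain_organisms.values()))
        pr.organism = orgs[0] if len(orgs) == 1 else "; ".join(orgs)
    return list(records.values())


def count_chains(record: ProteinRecord) -> str:
    """'single' iff the record names exactly one distinct chain identifier."""
    return "single" if len(set(record.chains)) == 1 else "multiple"


def render_description(record: ProteinRecord) -> str:
    """Fill the fixed description template; the raw sequence is excluded."""
    missing = [f for f, v in [("molecule_name", record.molecule_name),
                              ("organism", record.organism)] if not v]
    if missing:
        raise ValueError(f"cannot render description, missing fields: {missing}")
    return DESCRIPTION_TEMPLATE.format(
        pid=record.protein_id,
        length=record.sequence_length,
        chains=", ".join(record.chains),
        name=record.molecule_name,
        organism=record.organism,
    )


def _read_structure(text: str) -> gemmi.Structure:
    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise ValueError("no ATOM records found in PDB input")
    return st


_BACKBONE = ("N", "CA", "C", "O")


def pdb_to_residue_records(
    text: str, protein_id: str = "", atom_mode: str = "ca_only"
) -> ResidueCoordinateRecord:
    """Convert PDB text to the per-residue coordinate record.

    ``atom_mode='ca_only'`` keeps one [x, y, z] triple per residue (the CA
    atom); ``'backbone4'`` keeps four (N, CA, C, O).  Residues missing a
    required atom are skipped with a warning; residue order follows the file.
    """
    if atom_mode not in ("ca_only", "backbone4"):
        raise ValueError(f"unknown atom_mode {atom_mode!r}")
    wanted = ("CA",) if atom_mode == "ca_only" else _BACKBONE
    st = _read_structure(text)
    seq = []
    coords: list[list[list[float]]] = []
    for chain in st[0]:
        for res in chain:
            atoms = {a.name: a.pos for a in res}
            if any(w not in atoms for w in wanted):
                logger.warning("skipping residue %s %s%d: missing backbone atom",
                               res.name, chain.name, res.seqid.num)
                continue
            info = gemmi.find_tabulated_residue(res.name)
            one = info.one_letter_code.upper() if info else "X"
            seq.append(one if one.isalpha() else "X")
            coords.append([[round(atoms[w].x, 3), round(atoms[w].y, 3),
                            round(atoms[w].z, 3)] for w in wanted])
    return ResidueCoordinateRecord(ID=protein_id, seq="".join(seq), coords=coords)


def pdb_to_atom_graph(text: str, bond_cutoff: float = 1.9) -> AtomGraph:
    """Heavy-atom graph with edges between atoms at most ``bond_cutoff`` Å
    apart (default 1.9 Å, covering covalent bonds between C/N/O/S)."""
    st = _read_structure(text)
    elements, res_idx, xyz = [], [], []
    ri = -1
    for chain in st[0]:
        for res in chain:
            ri += 1
            for a in res:
                if a.element.is_hydrogen:
                    continue
                elements.append(a.element.name)
                res_idx.append(ri)
                xyz.append([a.pos.x, a.pos.y, a.pos.z])
    pts = np.asarray(xyz)
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=bond_cutoff)
    edges = {(min(i, j), max(i, j)) for i, j in pairs}
    return AtomGraph(elements=elements, residue_index=res_idx, edges=edges)


def pool_node_embeddings(node_matrix) -> np.ndarray:
    """Average-pool per-node embeddings into one fixed-size vector."""
    arr = np.asarray(node_matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("node matrix must be non-empty and 2-D")
    return arr.mean(axis=0)
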