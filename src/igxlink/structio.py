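"""Readers and writers for structures, sequences, and cross-link tables.

This module is the data backbone of the package: it defines the in-memory
containers (:class:`StructureModel`, :class:`Chain`, :class:`CrossLink`,
:class:`CrossLinkTable`) and the I/O boundary.  Structures are parsed with
gemmi (PDB and mmCIF), sequences with Biopython, and delimited cross-link
tables with pandas.

Conventions
-----------
* Coordinates are in Angstrom; residue numbers are 1-based author numbers.
* Cross-link positions are in full-sequence (UniProt/FASTA) numbering.  A
  per-chain integer offset reconciles the two numbering schemes:
  ``author_resnum = sequence_position + offset``.  Offsets can be derived
  from a FASTA record by exact subsequence matching (:func:`derive_offsets`).
* Only the first model of a multi-model file is read; for alternate
  locations the blank or 'A' altloc wins.
* A cross-link is identified by its canonical residue pair: the two
  (protein, position) endpoints sorted lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO


# --------------------------------------------------------------------------
# errors

class StructIOError(Exception):
    """Base class for I/O errors in this module."""


class StructureParseError(StructIOError):
    pass


class FormatError(StructIOError):
    pass


class SchemaError(StructIOError):
    pass


class RowError(StructIOError):
    pass


class OffsetError(StructIOError):
    pass


class EmptyTableError(StructIOError):
    pass


# --------------------------------------------------------------------------
# amino-acid alphabet

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}
AA_1TO3["X"] = "UNK"


# --------------------------------------------------------------------------
# containers

@dataclass
class Chain:
    """One polymer chain as a Cα trace.

    ``resnums`` are strictly increasing author residue numbers, ``aas`` the
    matching one-letter codes ('X' for non-standard), and ``coords`` the
    Cα coordinates with NaN rows where a residue has no Cα atom.
    """

    chain_id: str
    resnums: np.ndarray          # (n,) int
    aas: list[str]               # (n,) one-letter codes
    coords: np.ndarray           # (n, 3) float, NaN where Cα absent

    def __post_init__(self) -> None:
        self.resnums = np.asarray(self.resnums, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.resnums) != len(self.aas) or len(self.resnums) != len(self.coords):
            raise ValueError("resnums, aas and coords must have equal length")
        if len(self.resnums) > 1 and not np.all(np.diff(self.resnums) > 0):
            raise ValueError(
                f"residue numbers not strictly increasing in chain {self.chain_id!r}"
            )
        bad = [a for a in self.aas if a not in AA_1TO3]
        if bad:
            raise ValueError(f"unknown amino-acid codes {sorted(set(bad))!r}")
        self._index = {int(r): i for i, r in enumerate(self.resnums)}

    def __len__(self) -> int:
        return len(self.resnums)

    def has_residue(self, resnum: int) -> bool:
        return resnum in self._index

    def ca(self, resnum: int) -> np.ndarray | None:
        """Cα coordinate of a residue, or None if absent."""
        i = self._index.get(resnum)
        if i is None:
            return None
        xyz = self.coords[i]
        if np.any(np.isnan(xyz)):
            return None
        return xyz

    @property
    def sequence(self) -> str:
        return "".join(self.aas)


@dataclass
class StructureModel:
    """A set of chains with a chain → protein-accession map."""

    model_id: str
    chains: dict[str, Chain]
    chain_proteins: dict[str, str]

    def __post_init__(self) -> None:
        for cid in self.chains:
            self.chain_proteins.setdefault(cid, self.model_id)

    def chains_for(self, protein: str) -> list[str]:
        return [cid for cid, p in self.chain_proteins.items()
                if p == protein and cid in self.chains]

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def all_coords(self) -> np.ndarray:
        """Stack of all present Cα coordinates."""
        parts = [c.coords[~np.isnan(c.coords).any(axis=1)] for c in self.chains.values()]
        if not parts:
            return np.empty((0, 3))
        return np.vstack(parts)


@dataclass(frozen=True)
class CrossLink:
    """One identified residue-pair cross-link with its evidence metadata."""

    protein_a: str
    pos_a: int
    protein_b: str
    pos_b: int
    csm_count: int = 1
    replicate: int = 1
    condition: str = ""

    def __post_init__(self) -> None:
        if self.pos_a < 1 or self.pos_b < 1:
            raise ValueError("cross-link positions are 1-based and must be >= 1")
        if self.csm_count < 0:
            raise ValueError("csm_count must be non-negative")

    def canonical(self) -> "CrossLink":
        """Return the link with endpoints in lexicographic (protein, pos) order."""
        if (self.protein_a, self.pos_a) <= (self.protein_b, self.pos_b):
            return self
        return replace(
            self,
            protein_a=self.protein_b, pos_a=self.pos_b,
            protein_b=self.protein_a, pos_b=self.pos_a,
        )

    @property
    def key(self) -> tuple[str, int, str, int]:
        """Order-insensitive identity of the residue pair."""
        c = self.canonical()
        return (c.protein_a, c.pos_a, c.protein_b, c.pos_b)

    @property
    def is_self(self) -> bool:
        return self.protein_a == self.protein_b and self.pos_a == self.pos_b


@dataclass
class CrossLinkTable:
    """A collection of canonical cross-links with provenance."""

    links: list[CrossLink]
    provenance: str = ""

    def __post_init__(self) -> None:
        # canonicalize and drop exact duplicates within one replicate
        seen: set[tuple] = set()
        out = []
        for ln in self.links:
            c = ln.canonical()
            sig = (c.key, c.csm_count, c.replicate, c.condition)
            if sig in seen:
                continue
            seen.add(sig)
            out.append(c)
        self.links = out

    def __len__(self) -> int:
        return len(self.links)

    def unique_keys(self) -> set[tuple[str, int, str, int]]:
        return {ln.key for ln in self.links}

    def replicates(self) -> set[int]:
        return {ln.replicate for ln in self.links}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(l.protein_a, l.pos_a, l.protein_b, l.pos_b,
              l.csm_count, l.replicate, l.condition) for l in self.links],
            columns=["protein_a", "pos_a", "protein_b", "pos_b",
                     "csm_count", "replicate", "condition"],
        )


# --------------------------------------------------------------------------
# structure reading / writing

def _first_model_chains(st: gemmi.Structure) -> gemmi.Model:
    if len(st) == 0:
        raise StructureParseError(f"no models found in {st.name!r}")
    return st[0]


def read_structure(
    path: str | Path,
    format: str = "auto",
    chain_proteins: Mapping[str, str] | str | None = None,
) -> StructureModel:
    """Read a PDB/mmCIF file into a Cα-trace :class:`StructureModel`.

    Only the first model is used; HETATM records are ignored; for alternate
    locations the blank or 'A' altloc wins.  Residues without a Cα atom are
    retained with an absent coordinate.

    Parameters
    ----------
    format:
        One of ``pdb``, ``mmcif`` or ``auto`` (detect from the file).
    chain_proteins:
        Chain-id → protein-accession map.  A single string maps every chain
        to that accession; None maps every chain to the file stem.
    """
    path = Path(path)
    fmt_map = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }
    if format not in fmt_map:
        raise FormatError(f"unknown structure format {format!r}; use pdb/mmcif/auto")
    if not path.exists():
        raise StructureParseError(f"file not found: {path}")
    if path.stat().st_size == 0:
        raise StructureParseError(f"empty file: {path} (line 1)")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    model = _first_model_chains(st)

    chains: dict[str, Chain] = {}
    for ch in model:
        resnums, aas, coords = [], [], []
        for res in ch:
            if res.het_flag == "H":
                continue
            aa = AA_3TO1.get(res.name.upper(), "X")
            ca = None
            for atom in res:
                if atom.name == "CA" and atom.altloc in ("\0", "", "A"):
                    ca = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    break
            resnums.append(res.seqid.num)
            aas.append(aa)
            coords.append(ca if ca is not None else np.full(3, np.nan))
        if not resnums:
            continue
        # keep only the first occurrence if numbering repeats (e.g. insertions)
        order = np.argsort(resnums, kind="stable")
        uniq: dict[int, int] = {}
        for i in order:
            uniq.setdefault(resnums[i], i)
        idx = sorted(uniq.values(), key=lambda i: resnums[i])
        chains[ch.name] = Chain(
            chain_id=ch.name,
            resnums=np.array([resnums[i] for i in idx]),
            aas=[aas[i] for i in idx],
            coords=np.array([coords[i] for i in idx]),
        )
    if not chains:
        raise StructureParseError(f"no polymer chains with residues in {path}")

    model_id = path.stem
    if chain_proteins is None:
        cp = {cid: model_id for cid in chains}
    elif isinstance(chain_proteins, str):
        cp = {cid: chain_proteins for cid in chains}
    else:
        cp = dict(chain_proteins)
    return StructureModel(model_id=model_id, chains=chains, chain_proteins=cp)


def write_structure(model: StructureModel, path: str | Path) -> Path:
    """Write a Cα-trace :class:`StructureModel` as a standard PDB file."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = model.model_id
    md = gemmi.Model("1")
    for cid, chain in model.chains.items():
        gch = gemmi.Chain(cid)
        for resnum, aa, xyz in zip(chain.resnums, chain.aas, chain.coords):
            res = gemmi.Residue()
            res.name = AA_1TO3.get(aa, "UNK")
            res.seqid = gemmi.SeqId(int(resnum), " ")
            if not np.any(np.isnan(xyz)):
                atom = gemmi.Atom()
                atom.name = "CA"
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                res.add_atom(atom)
            gch.add_residue(res)
        md.add_chain(gch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))
    return path


# --------------------------------------------------------------------------
# sequences and numbering offsets

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an accession → sequence map."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise StructIOError(f"no FASTA records in {path}")
    return records


def derive_offsets(
    model: StructureModel,
    sequences: Mapping[str, str],
) -> dict[str, int]:
    """Derive per-chain numbering offsets by exact subsequence matching.

    For each chain whose protein has a sequence, the chain's one-letter
    sequence is located in the full sequence exactly; the offset satisfies
    ``author_resnum = sequence_position + offset``.  Ambiguous (multiple
    matches) or failed matches raise :class:`OffsetError` rather than guess.
    """
    offsets: dict[str, int] = {}
    for cid, chain in model.chains.items():
        protein = model.chain_proteins.get(cid)
        if protein not in sequences:
            continue
        full = sequences[protein]
        sub = chain.sequence
        first = int(chain.resnums[0])
        start = full.find(sub)
        if start < 0:
            raise OffsetError(
                f"chain {cid!r} sequence not found in FASTA record {protein!r}"
            )
        if full.find(sub, start + 1) >= 0:
            raise OffsetError(
                f"chain {cid!r} sequence matches record {protein!r} more than once;"
                " supply an explicit offset"
            )
        # sequence position of the chain's first residue is start+1 (1-based)
        offsets[cid] = first - (start + 1)
    return offsets


# --------------------------------------------------------------------------
# cross-link tables

#: Column-name presets.  Keys are the canonical field names; values the
#: column headers expected in the file.
DIALECTS: dict[str, dict[str, str]] = {
    "generic": {
        "protein_a": "protein_a", "pos_a": "pos_a",
        "protein_b": "protein_b", "pos_b": "pos_b",
        "csm_count": "csm_count", "replicate": "replicate",
        "condition": "condition",
    },
    # XlinkX-style residue-pair export
    "xlinkx": {
        "protein_a": "Protein Accession A", "pos_a": "Leading Protein Position A",
        "protein_b": "Protein Accession B", "pos_b": "Leading Protein Position B",
        "csm_count": "# CSMs", "replicate": "Replicate",
        "condition": "Condition",
    },
}

_REQUIRED = ("protein_a", "pos_a", "protein_b", "pos_b")
_OPTIONAL_DEFAULTS = {"csm_count": 1, "replicate": 1, "condition": ""}


def read_crosslink_table(
    path: str | Path,
    dialect: str | Mapping[str, str] = "generic",
) -> CrossLinkTable:
    """Read a delimited cross-link table (comma/tab autodetected).

    ``dialect`` is a preset name (:data:`DIALECTS`) or an explicit mapping
    from canonical field names to column headers.  Missing required columns
    raise :class:`SchemaError`; a non-integer position raises
    :class:`RowError` with the offending row number.  Self-links are kept
    (flagged via :attr:`CrossLink.is_self`), never silently dropped.
    """
    path = Path(path)
    if isinstance(dialect, str):
        try:
            colmap = DIALECTS[dialect]
        except KeyError:
            raise SchemaError(
                f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
            ) from None
    else:
        colmap = dict(dialect)

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise StructIOError(f"cannot parse table {path}: {exc}") from exc

    missing = [colmap[f] for f in _REQUIRED
               if f in colmap and colmap[f] not in df.columns]
    absent = [f for f in _REQUIRED if f not in colmap]
    if missing or absent:
        raise SchemaError(
            f"missing required columns in {path}: "
            f"{missing + [f'<no mapping for {f}>' for f in absent]}"
        )

    links: list[CrossLink] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rowd = dict(zip(df.columns, row))
        vals = {}
        for f in _REQUIRED:
            vals[f] = rowd[colmap[f]]
        for f, dflt in _OPTIONAL_DEFAULTS.items():
            col = colmap.get(f)
            vals[f] = rowd[col] if col in df.columns else dflt
            if pd.isna(vals[f]):
                vals[f] = dflt
        try:
            pos_a, pos_b = int(vals["pos_a"]), int(vals["pos_b"])
            if float(vals["pos_a"]) != pos_a or float(vals["pos_b"]) != pos_b:
                raise ValueError
        except (TypeError, ValueError):
            raise RowError(
                f"non-integer position in {path} row {row_no}: "
                f"{vals['pos_a']!r}/{vals['pos_b']!r}"
            ) from None
        links.append(CrossLink(
            protein_a=str(vals["protein_a"]), pos_a=pos_a,
            protein_b=str(vals["protein_b"]), pos_b=pos_b,
            csm_count=int(vals["csm_count"]), replicate=int(vals["replicate"]),
            condition=str(vals["condition"]),
        ))
    return CrossLinkTable(links=links, provenance=f"{path}:{dialect}")


def export_links(
    obj: "CrossLinkTable | Iterable",
    path: str | Path,
    flavor: str = "tsv",
) -> Path:
    """Export cross-links as canonical TSV, xiNET CSV, or a per-residue summary.

    ``per_residue_summary`` emits one row per cross-linked residue with the
    number of distinct links touching it and its summed CSM count — the
    input layout of a circos-style residue plot.
    """
    path = Path(path)
    if isinstance(obj, CrossLinkTable):
        links = obj.links
    else:
        links = [ln.canonical() for ln in obj]
    if not links:
        raise EmptyTableError("nothing to export: empty link table")

    if flavor == "tsv":
        frame = CrossLinkTable(links=list(links)).to_frame()
        frame = frame.sort_values(list(frame.columns), kind="stable")
        frame.to_csv(path, sep="\t", index=False)
    elif flavor == "xinet":
        rows = sorted({(l.protein_a, l.protein_b, l.pos_a, l.pos_b, l.csm_count)
                       for l in links})
        pd.DataFrame(rows, columns=["Protein1", "Protein2",
                                    "Residue1", "Residue2", "Score"]
                     ).to_csv(path, index=False)
    elif flavor == "per_residue_summary":
        # count unique links and sum CSMs per residue endpoint
        counts: dict[tuple[str, int], set] = {}
        csms: dict[tuple[str, int], int] = {}
        for l in links:
            for endpoint in {(l.protein_a, l.pos_a), (l.protein_b, l.pos_b)}:
                counts.setdefault(endpoint, set()).add(l.key)
                csms[endpoint] = csms.get(endpoint, 0) + l.csm_count
        rows = [(p, r, len(counts[(p, r)]), csms[(p, r)])
                for (p, r) in sorted(counts)]
        pd.DataFrame(rows, columns=["protein", "residue",
                                    "n_links", "total_csms"]
                     ).to_csv(path, sep="\t", index=False)
    else:
        raise FormatError(f"unknown export flavor {flavor!r}")
    return path
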