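"""PDB-format structure I/O and backbone-chain extraction.

The module reads the fixed-column PDB dialect (ATOM/HETATM/MODEL/TER/REMARK),
resolves alternate locations deterministically, and exposes :class:`BackboneChain`,
the ordered list of residues carrying the four backbone atoms (N, CA, C, O) that
every downstream algorithm operates on.  Internal residue indexing is 0-based and
dense; author numbering (residue number + insertion code) is kept only as
metadata, so no other module ever does insertion-code arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Peptide-bond C(i)–N(i+1) distances at or above this are flagged as chain breaks.
#: The covalent bond is ~1.33 Å; 2.5 Å tolerates poor models while catching gaps.
CHAIN_BREAK_CN = 2.5


class PDBParseError(ValueError):
    """Raised for malformed PDB records; the message names the offending line."""


@dataclass
class AtomRecord:
    name: str
    coords: np.ndarray  # shape (3,), Å
    element: str = ""
    bfactor: float = 0.0
    occupancy: float = 1.0
    altloc: str = " "

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Residue:
    seq_id: int                 # author residue number
    chain_id: str
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    icode: str = " "            # author insertion code

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in BACKBONE_ATOMS)

    @property
    def author_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.icode)


@dataclass
class BackboneChain:
    """Ordered residues, each guaranteed to carry N, CA, C and O.

    ``breaks`` holds internal indices i where the C(i)–N(i+1) distance is at
    least :data:`CHAIN_BREAK_CN`, i.e. where the chain is not covalently
    continuous.  Internal positions are dense 0-based integers.
    """

    residues: list[Residue]
    source_id: str = ""
    breaks: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        for r in self.residues:
            if not r.has_backbone():
                raise ValueError(
                    f"residue {r.chain_id}{r.seq_id}{r.icode.strip()} lacks a backbone atom"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def backbone_coords(self) -> np.ndarray:
        """(n, 4, 3) array of N, CA, C, O coordinates per residue."""
        out = np.empty((len(self.residues), 4, 3))
        for i, r in enumerate(self.residues):
            for j, name in enumerate(BACKBONE_ATOMS):
                out[i, j] = r.atom(name).coords
        return out

    def ca_coords(self) -> np.ndarray:
        return np.array([r.atom("CA").coords for r in self.residues])

    def with_coords(self, coords: np.ndarray) -> "BackboneChain":
        """Copy of the chain with backbone coordinates replaced ((n, 4, 3))."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.residues), 4, 3):
            raise ValueError(f"expected coords of shape ({len(self)}, 4, 3)")
        new_res = []
        for r, rc in zip(self.residues, coords):
            atoms = []
            for a in r.atoms:
                if a.name in BACKBONE_ATOMS:
                    atoms.append(replace(a, coords=rc[BACKBONE_ATOMS.index(a.name)].copy()))
                else:
                    atoms.append(replace(a, coords=a.coords.copy()))
            new_res.append(replace(r, atoms=atoms))
        return BackboneChain(new_res, source_id=self.source_id, breaks=self.breaks)

    @staticmethod
    def from_coords(
        coords: np.ndarray,
        source_id: str = "synthetic",
        chain_id: str = "A",
        res_name: str = "ALA",
        start_seq: int = 1,
        res_names: list[str] | None = None,
    ) -> "BackboneChain":
        """Build a chain from an (n, 4, 3) array of N/CA/C/O coordinates."""
        coords = np.asarray(coords, dtype=float)
        residues = []
        for i, rc in enumerate(coords):
            name = res_names[i] if res_names else res_name
            atoms = [
                AtomRecord(name=an, coords=rc[j], element=an[0])
                for j, an in enumerate(BACKBONE_ATOMS)
            ]
            residues.append(Residue(seq_id=start_seq + i, chain_id=chain_id,
                                    res_name=name, atoms=atoms))
        return to_backbone_chain(residues, source_id=source_id)


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, str, int, str, str, bool]:
    """Parse one ATOM/HETATM record; returns (atom, chain, resseq, icode, resname, is_het)."""
    try:
        name = line[12:16].strip()
        altloc = line[16] if len(line) > 16 else " "
        res_name = line[17:20].strip()
        chain_id = line[21] if len(line) > 21 else " "
        seq_id = int(line[22:26])
        icode = line[26] if len(line) > 26 else " "
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_s = line[54:60].strip()
        b_s = line[60:66].strip()
        occupancy = float(occ_s) if occ_s else 1.0
        bfactor = float(b_s) if b_s else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    if not name:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: empty atom name")
    atom = AtomRecord(name=name, coords=np.array([x, y, z]), element=element,
                      bfactor=bfactor, occupancy=occupancy, altloc=altloc)
    return atom, chain_id, seq_id, icode, res_name, line.startswith("HETATM")


def _resolve_altlocs(residue: Residue) -> Residue:
    """Keep one atom per name: highest occupancy, ties broken by altloc code.

    Blank altloc sorts before 'A', so an unconflicted atom always survives.
    The result is independent of record order within the residue.
    """
    by_name: dict[str, AtomRecord] = {}
    for a in sorted(residue.atoms, key=lambda a: (-a.occupancy, a.altloc)):
        by_name.setdefault(a.name, a)
    # preserve first-seen atom-name order from the file
    seen: list[str] = []
    for a in residue.atoms:
        if a.name not in seen:
            seen.append(a.name)
    residue.atoms = [by_name[n] for n in seen]
    return residue


def parse_pdb(
    text: str,
    model: int | None = None,
    include_hetatm: bool = False,
) -> list[tuple[str, list[Residue]]]:
    """Parse PDB-format text into per-chain residue lists, in file order.

    Alternate locations are resolved to the highest-occupancy conformer
    (alphabetically first altloc on ties).  HETATM residues are excluded
    unless ``include_hetatm``.  With multiple MODEL blocks, ``model`` selects
    one by its serial number (default: the first encountered).
    """
    models_seen: list[int] = []
    current_model: int | None = None
    first_model: int | None = None
    chains: dict[str, dict[tuple[int, str], Residue]] = {}
    chain_order: list[str] = []

    def wanted(m: int | None) -> bool:
        if model is None:
            return first_model is None or m == first_model
        return m == model

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            try:
                current_model = int(line[6:].split()[0])
            except (ValueError, IndexError) as exc:
                raise PDBParseError(f"malformed MODEL record at line {lineno}") from exc
            models_seen.append(current_model)
            if first_model is None:
                first_model = current_model
        elif rec in ("ATOM  ", "HETATM"):
            if current_model is not None and not wanted(current_model):
                continue
            atom, chain_id, seq_id, icode, res_name, is_het = _parse_atom_line(line, lineno)
            if is_het and not include_hetatm:
                continue
            if chain_id not in chains:
                chains[chain_id] = {}
                chain_order.append(chain_id)
            key = (seq_id, icode)
            res = chains[chain_id].get(key)
            if res is None:
                res = Residue(seq_id=seq_id, chain_id=chain_id, res_name=res_name, icode=icode)
                chains[chain_id][key] = res
            res.atoms.append(atom)

    if model is not None and models_seen and model not in models_seen:
        raise PDBParseError(f"model {model} not found (models present: {sorted(set(models_seen))})")
    if model is not None and not models_seen:
        raise PDBParseError("model selection requested but file has no MODEL records")

    out: list[tuple[str, list[Residue]]] = []
    for cid in chain_order:
        residues = [_resolve_altlocs(r) for r in chains[cid].values()]
        out.append((cid, residues))
    return out


def to_backbone_chain(
    residues: list[Residue],
    strict: bool = False,
    source_id: str = "",
) -> BackboneChain:
    """Filter residues to those with a complete N/CA/C/O backbone.

    Incomplete residues are dropped (``strict=False``) or raise
    (``strict=True``).  Chain breaks — C(i)–N(i+1) ≥ 2.5 Å, including gaps
    created by dropping a residue — are flagged in ``breaks``.
    """
    kept: list[Residue] = []
    for r in residues:
        if r.has_backbone():
            kept.append(r)
        elif strict:
            raise ValueError(
                f"residue {r.chain_id}{r.seq_id}{r.icode.strip()} "
                f"({r.res_name}) is missing a backbone atom"
            )
    if not kept:
        raise ValueError("no complete backbone residues")
    breaks = set()
    for i in range(len(kept) - 1):
        d = float(np.linalg.norm(kept[i + 1].atom("N").coords - kept[i].atom("C").coords))
        if d >= CHAIN_BREAK_CN:
            breaks.add(i)
    return BackboneChain(kept, source_id=source_id, breaks=frozenset(breaks))


def chains_from_pdb(
    text: str,
    chain_id: str | None = None,
    model: int | None = None,
    strict: bool = False,
    source_id: str = "",
) -> BackboneChain:
    """Parse PDB text and return one chain as a BackboneChain (default: chain A
    if present, else the first chain)."""
    parsed = parse_pdb(text, model=model)
    if not parsed:
        raise PDBParseError("no ATOM records found")
    ids = [cid for cid, _ in parsed]
    if chain_id is None:
        chain_id = "A" if "A" in ids else ids[0]
    for cid, residues in parsed:
        if cid == chain_id:
            return to_backbone_chain(residues, strict=strict,
                                     source_id=source_id or f"pdb:{cid}")
    raise PDBParseError(f"chain {chain_id!r} not found (chains present: {ids})")


def write_pdb(chains, remarks: list[str] | None = None) -> str:
    """Serialize BackboneChains (or objects with a ``.chain`` and provenance,
    e.g. a ChimeraModel) to PDB-format text.

    Atom serials are dense from 1; a TER record follows each chain; chimera
    provenance (insert/linker residue numbers) is emitted as REMARK 999 lines.
    Round-tripping through :func:`parse_pdb` preserves coordinates to the
    3 decimals the format carries.
    """
    if not chains:
        raise ValueError("no chains to write")
    lines: list[str] = []
    for rm in remarks or []:
        lines.append(f"REMARK 900 {rm}"[:80])

    serial = 1
    for item in chains:
        chain = item
        provenance = None
        if hasattr(item, "chain") and hasattr(item, "provenance"):
            chain, provenance = item.chain, item.provenance
        if provenance is not None:
            for label in ("insert", "linker"):
                nums = [str(chain.residues[i].seq_id)
                        for i, p in enumerate(provenance) if p == label]
                if nums:
                    lines.append(f"REMARK 999 {label.upper()} RESIDUES {' '.join(nums)}"[:80])
        for res in chain.residues:
            for atom in res.atoms:
                name = atom.name
                # standard PDB alignment: 1-3 char names start in column 14
                aname = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {aname}{atom.altloc if atom.altloc.strip() else ' '}"
                    f"{res.res_name:>3s} {res.chain_id}{res.seq_id:4d}{res.icode}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {chain.residues[-1].res_name:>3s} "
                     f"{chain.residues[-1].chain_id}{chain.residues[-1].seq_id:4d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
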