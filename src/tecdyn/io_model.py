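"""Structures, trajectories, file I/O and the atom-selection mini-language.

This module defines the in-memory model every other module operates on:

* :class:`Atom` / :class:`Structure` — a topology plus one coordinate set;
* :class:`Trajectory` — ordered frames sharing a topology, with a time stride;
* :func:`read_structure` / :func:`write_structure` for fixed-column PDB and a
  plain XYZ dialect;
* :func:`read_trajectory` / :func:`write_trajectory` for multi-model PDB and
  XYZ trajectories;
* :func:`select`, a small boolean selection language
  (``chain A and resid 1219-1265 and not water``).

Atoms are addressed by *keys* of the form ``"chain:resid:name"`` (insertion
code, when present, is appended to the resid, e.g. ``"A:52A:CA"``).  Prime
characters in atom names are normalized so that ``C3*`` and ``C3'`` refer to
the same atom.

Conventions: coordinates in Angstrom, residue numbering 1-based as in PDB,
selection ranges inclusive on both ends, default trajectory stride 20 ps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "AtomSelection",
    "ParseError",
    "SelectionError",
    "WATER_RESNAMES",
    "DEFAULT_FRAME_INTERVAL_PS",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select",
]

#: Residue names recognized as water (TIP3P solvent appears under several).
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})

#: Default time between trajectory frames, ps.
DEFAULT_FRAME_INTERVAL_PS = 20.0


class ParseError(ValueError):
    """A structure or trajectory file violated its format."""


class SelectionError(ValueError):
    """A selection expression could not be parsed."""


def normalize_atom_name(name: str) -> str:
    """Map PDB-dialect primes: ``C3*`` -> ``C3'``."""
    return name.strip().replace("*", "'")


@dataclass(frozen=True)
class Atom:
    """One atom of a structure.

    ``het`` records whether the atom came from (or should be written as) a
    HETATM record; ``icode`` is the PDB insertion code ('' if none).
    """

    serial: int
    name: str
    resname: str
    chain: str
    resid: int
    element: str = ""
    het: bool = False
    icode: str = ""

    @property
    def resid_key(self) -> str:
        return f"{self.resid}{self.icode}"

    def key(self) -> str:
        return f"{self.chain}:{self.resid_key}:{self.name}"

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_RESNAMES


class Structure:
    """An ordered list of atoms plus one coordinate set (n_atoms x 3, A)."""

    def __init__(self, atoms, coords, title: str = "", box=None):
        self.atoms: list[Atom] = list(atoms)
        self.coords = np.asarray(coords, dtype=float).reshape(len(self.atoms), 3)
        if not self.atoms:
            raise ValueError("a Structure must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self.title = title
        self.box = None if box is None else np.asarray(box, dtype=float)
        self._key_index: dict[str, int] = {}
        for i, a in enumerate(self.atoms):
            self._key_index.setdefault(a.key(), i)
        # Column arrays used by the selection evaluator.
        self.chains = np.array([a.chain for a in self.atoms])
        self.resids = np.array([a.resid for a in self.atoms])
        self.names = np.array([a.name for a in self.atoms])
        self.resnames = np.array([a.resname for a in self.atoms])
        self.elements = np.array([a.element for a in self.atoms])

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def index_of(self, key: str) -> int:
        """Index of the atom addressed by ``"chain:resid:name"``.

        Raises KeyError naming the missing atom.
        """
        chain, resid, name = key.split(":")
        k = f"{chain}:{resid}:{normalize_atom_name(name)}"
        if k not in self._key_index:
            raise KeyError(f"atom not found: {key!r}")
        return self._key_index[k]

    def position(self, key: str) -> np.ndarray:
        return self.coords[self.index_of(key)]

    def with_coords(self, coords) -> "Structure":
        return Structure(self.atoms, coords, title=self.title, box=self.box)

    def residue_atom_map(self) -> dict:
        """Cached map ``"chain:resid" -> [atom indices]`` in topology order."""
        if not hasattr(self, "_res_atom_map"):
            m: dict[str, list[int]] = {}
            for i, a in enumerate(self.atoms):
                m.setdefault(f"{a.chain}:{a.resid_key}", []).append(i)
            self._res_atom_map = m
        return self._res_atom_map

    def residue_groups(self):
        """Yield (chain, resid_key, resname, [atom indices]) in topology order."""
        seen: dict[tuple, list[int]] = {}
        order = []
        for i, a in enumerate(self.atoms):
            rk = (a.chain, a.resid_key, a.resname)
            if rk not in seen:
                seen[rk] = []
                order.append(rk)
            seen[rk].append(i)
        for rk in order:
            yield rk[0], rk[1], rk[2], seen[rk]


class Trajectory:
    """Ordered coordinate frames over a shared topology.

    ``frames`` is an (n_frames, n_atoms, 3) array; ``frame_interval`` is the
    time between consecutive frames in ps.
    """

    def __init__(self, topology: Structure, frames, frame_interval: float = DEFAULT_FRAME_INTERVAL_PS):
        self.topology = topology
        frames = np.asarray(frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[None, :, :]
        if frames.shape[1] != topology.n_atoms:
            raise ValueError(
                f"frame atom count {frames.shape[1]} != topology atom count {topology.n_atoms}"
            )
        if frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.frames = frames
        self.frame_interval = float(frame_interval)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass
class AtomSelection:
    """A selection expression together with its resolved atom indices."""

    expression: str
    resolved: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __len__(self):
        return len(self.resolved)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_pdb_atom_line(line: str, lineno: int):
    try:
        serial = int(line[6:11])
        name = normalize_atom_name(line[12:16])
        altloc = line[16:17].strip()
        resname = line[17:21].strip()
        chain = line[21:22].strip() or "A"
        resid = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 77 else ""
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed PDB record at line {lineno}: {line.rstrip()!r}") from exc
    if not element:
        element = _guess_element(name, resname)
    return {
        "serial": serial,
        "name": name,
        "altloc": altloc,
        "resname": resname,
        "chain": chain,
        "resid": resid,
        "icode": icode,
        "xyz": (x, y, z),
        "occupancy": occupancy,
        "element": element,
        "het": line.startswith("HETATM"),
    }


def _guess_element(name: str, resname: str) -> str:
    if resname == "MG" or name == "MG":
        return "MG"
    stripped = name.lstrip("0123456789'")
    return stripped[:1].upper() if stripped else ""


def _resolve_altlocs(records):
    """Keep one record per (chain, resid, icode, name): highest occupancy,
    ties broken alphabetically by altloc ('' sorts first)."""
    best: dict[tuple, dict] = {}
    order: list[tuple] = []
    for rec in records:
        k = (rec["chain"], rec["resid"], rec["icode"], rec["name"])
        if k not in best:
            best[k] = rec
            order.append(k)
        else:
            cur = best[k]
            if (rec["occupancy"], _altloc_rank(rec["altloc"])) > (
                cur["occupancy"],
                _altloc_rank(cur["altloc"]),
            ):
                best[k] = rec
    return [best[k] for k in order]


def _altloc_rank(altloc: str):
    # Higher rank wins; alphabetical preference means 'A' beats 'B'.
    return -ord(altloc) if altloc else 1


def _records_to_structure(records, title: str = "") -> Structure:
    records = _resolve_altlocs(records)
    atoms = [
        Atom(
            serial=r["serial"],
            name=r["name"],
            resname=r["resname"],
            chain=r["chain"],
            resid=r["resid"],
            element=r["element"],
            het=r["het"],
            icode=r["icode"],
        )
        for r in records
    ]
    coords = np.array([r["xyz"] for r in records], dtype=float)
    return Structure(atoms, coords, title=title)


def _read_pdb_models(path):
    """All models in a PDB file as lists of atom records, plus the title."""
    models = []
    current = []
    in_model = False
    title = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                current.append(_parse_pdb_atom_line(line, lineno))
            elif rec == "MODEL ":
                if in_model and current:
                    models.append(current)
                    current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec.startswith("TITLE"):
                title += line[10:].rstrip() if len(line) > 10 else ""
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise ParseError(f"no ATOM/HETATM records found in {path}")
    return models, title.strip()


def read_structure(path, format: str = "pdb") -> Structure:
    """Read a structure file.

    PDB: all ATOM/HETATM records are retained (waters and ions included);
    altlocs are resolved to the highest-occupancy conformer, ties broken
    alphabetically.  For multi-model files the first model is used.

    XYZ: element symbols become atom names; residues are numbered serially.
    """
    path = Path(path)
    if format == "pdb":
        models, title = _read_pdb_models(path)
        return _records_to_structure(models[0], title=title)
    if format == "xyz":
        frames, comments = _read_xyz_frames(path)
        n = frames[0].shape[0]
        elems = comments[0].get("elements")
        atoms = [
            Atom(serial=i + 1, name=elems[i], resname="UNK", chain="A", resid=i + 1,
                 element=elems[i])
            for i in range(n)
        ]
        return Structure(atoms, frames[0], title=comments[0].get("comment", ""))
    raise ValueError(f"unsupported structure format: {format!r}")


def write_structure(structure: Structure, path, format: str = "pdb") -> None:
    """Write a structure; PDB coordinates are emitted to 3 decimals."""
    path = Path(path)
    if format == "pdb":
        with open(path, "w") as fh:
            if structure.title:
                fh.write(f"TITLE     {structure.title}\n")
            _write_pdb_model(fh, structure.atoms, structure.coords)
            fh.write("END\n")
    elif format == "xyz":
        with open(path, "w") as fh:
            _write_xyz_frame(fh, structure, structure.coords, comment=structure.title or "frame 0")
    else:
        raise ValueError(f"unsupported structure format: {format!r}")


def _pdb_atom_line(atom: Atom, xyz) -> str:
    if atom.resid > 9999 or atom.resid < -999:
        raise ValueError(f"resid {atom.resid} not encodable in fixed-column PDB")
    if atom.serial > 99999:
        raise ValueError(f"serial {atom.serial} not encodable in fixed-column PDB")
    if any(abs(c) >= 10000 for c in xyz):
        raise ValueError("coordinate magnitude not encodable in fixed-column PDB")
    record = "HETATM" if atom.het else "ATOM  "
    name = atom.name
    # PDB convention: 1-3 char names start in column 14 unless 2-char element.
    if len(name) < 4 and len(atom.element) < 2:
        name_f = f" {name:<3s}"
    else:
        name_f = f"{name:<4s}"
    return (
        f"{record}{atom.serial:>5d} {name_f} {atom.resname:<3.3s} {atom.chain:1.1s}"
        f"{atom.resid:>4d}{atom.icode:1.1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2.2s}\n"
    )


def _write_pdb_model(fh, atoms, coords):
    for atom, xyz in zip(atoms, coords):
        fh.write(_pdb_atom_line(atom, xyz))


# ---------------------------------------------------------------------------
# XYZ dialect: "<count>\n<comment [t= <ps>]>\n<element x y z>..." per frame
# ---------------------------------------------------------------------------

def _read_xyz_frames(path):
    frames = []
    comments = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"expected atom count at line {i + 1} of XYZ file") from exc
        comment = lines[i + 1].rstrip("\n") if i + 1 < len(lines) else ""
        coords = np.zeros((count, 3))
        elements = []
        for j in range(count):
            lineno = i + 2 + j
            if lineno >= len(lines):
                raise ParseError(f"truncated XYZ frame at line {lineno + 1}")
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ParseError(f"malformed XYZ atom line at line {lineno + 1}")
            elements.append(parts[0])
            try:
                coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise ParseError(f"malformed XYZ atom line at line {lineno + 1}") from exc
        m = re.search(r"t=\s*([-+0-9.eE]+)", comment)
        comments.append(
            {
                "comment": comment,
                "time_ps": float(m.group(1)) if m else None,
                "elements": elements,
            }
        )
        frames.append(coords)
        i += 2 + count
    if not frames:
        raise ParseError(f"no frames found in XYZ file {path}")
    return frames, comments


def _write_xyz_frame(fh, structure: Structure, coords, comment: str):
    fh.write(f"{structure.n_atoms}\n{comment}\n")
    for atom, xyz in zip(structure.atoms, coords):
        el = atom.element or atom.name[:1]
        fh.write(f"{el:<3s} {xyz[0]:14.6f} {xyz[1]:14.6f} {xyz[2]:14.6f}\n")


def read_trajectory(
    topology: Structure,
    path,
    dialect: str = "multi-model-pdb",
    frame_interval: float = DEFAULT_FRAME_INTERVAL_PS,
) -> Trajectory:
    """Read trajectory frames against a known topology.

    Every frame must carry exactly ``topology.n_atoms`` coordinates; a
    mismatch raises ParseError naming the offending frame.  The frame
    interval is taken from the caller (default 20 ps).
    """
    path = Path(path)
    if dialect == "multi-model-pdb":
        models, _ = _read_pdb_models(path)
        frames = []
        for k, model in enumerate(models):
            if len(model) != topology.n_atoms:
                raise ParseError(
                    f"frame {k}: atom count {len(model)} != topology {topology.n_atoms}"
                )
            frames.append(np.array([r["xyz"] for r in model], dtype=float))
    elif dialect == "xyz":
        raw, comments = _read_xyz_frames(path)
        frames = []
        for k, coords in enumerate(raw):
            if coords.shape[0] != topology.n_atoms:
                raise ParseError(
                    f"frame {k}: atom count {coords.shape[0]} != topology {topology.n_atoms}"
                )
            frames.append(coords)
        times = [c["time_ps"] for c in comments]
        if len(times) >= 2 and times[0] is not None and times[1] is not None:
            dt = times[1] - times[0]
            if dt > 0:
                frame_interval = dt
    else:
        raise ValueError(f"unsupported trajectory dialect: {dialect!r}")
    return Trajectory(topology, np.stack(frames), frame_interval=frame_interval)


def write_trajectory(traj: Trajectory, path, dialect: str = "multi-model-pdb") -> None:
    path = Path(path)
    if dialect == "multi-model-pdb":
        with open(path, "w") as fh:
            for k in range(traj.n_frames):
                fh.write(f"MODEL     {k + 1:>4d}\n")
                _write_pdb_model(fh, traj.topology.atoms, traj.frames[k])
                fh.write("ENDMDL\n")
            fh.write("END\n")
    elif dialect == "xyz":
        with open(path, "w") as fh:
            for k in range(traj.n_frames):
                t = k * traj.frame_interval
                _write_xyz_frame(fh, traj.topology, traj.frames[k], comment=f"t= {t:.3f} ps")
    else:
        raise ValueError(f"unsupported trajectory dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

_CLAUSE_KEYWORDS = {"chain", "resid", "resname", "name", "element"}


class _Parser:
    """Recursive-descent parser for the selection grammar.

    expr   := term ('or' term)*
    term   := factor ('and' factor)*
    factor := 'not' factor | '(' expr ')' | clause
    clause := chain V | resid RANGES | resname V | name V | element V | water
    """

    def __init__(self, expression: str, structure: Structure):
        self.expression = expression
        self.tokens = [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(expression)]
        self.pos = 0
        self.s = structure

    def _error(self, msg):
        at = self.tokens[self.pos][1] if self.pos < len(self.tokens) else len(self.expression)
        raise SelectionError(f"{msg} at position {at} in {self.expression!r}")

    def peek(self):
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        if tok is None:
            self._error("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionError("empty selection expression")
        mask = self.expr()
        if self.peek() is not None:
            self._error(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self):
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self):
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self):
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.peek() != ")":
                self._error("expected ')'")
            self.take()
            return mask
        return self.clause()

    def clause(self):
        tok = self.take()
        if tok == "water":
            return np.isin(self.s.resnames, list(WATER_RESNAMES))
        if tok in _CLAUSE_KEYWORDS:
            val = self.take()
            if tok == "chain":
                return self.s.chains == val
            if tok == "resname":
                return self.s.resnames == val
            if tok == "name":
                return self.s.names == normalize_atom_name(val)
            if tok == "element":
                return self.s.elements == val.upper()
            if tok == "resid":
                return self._resid_mask(val)
        self.pos -= 1
        self._error(f"unknown clause {tok!r}")

    def _resid_mask(self, val: str):
        mask = np.zeros(self.s.n_atoms, dtype=bool)
        for part in val.split(","):
            m = re.fullmatch(r"(-?\d+)-(-?\d+)", part)
            if m:
                lo, hi = int(m.group(1)), int(m.group(2))
                mask |= (self.s.resids >= lo) & (self.s.resids <= hi)
            else:
                try:
                    mask |= self.s.resids == int(part)
                except ValueError:
                    self.pos -= 1
                    self._error(f"bad resid value {part!r}")
        return mask


def select(structure: Structure, expression: str) -> AtomSelection:
    """Resolve a selection expression to atom indices in topology order.

    A syntactically valid expression matching nothing yields an empty
    selection (not an error); syntax errors raise :class:`SelectionError`
    with the character position.
    """
    mask = _Parser(expression, structure).parse()
    return AtomSelection(expression=expression, resolved=np.nonzero(mask)[0])
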