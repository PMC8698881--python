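"""Readers and writers for the tool's on-disk formats.

Three formats are handled:

* **PDB atomic models** — HELIX/SHEET annotations plus Cα ATOM records give
  the model-side SSEs. Parsed with :mod:`gemmi`.
* **Stick trace files** — plain text, one ``x y z`` axis point per line,
  blank line between sticks, ``#`` comments. This is the exchange format
  for map-side SSE detections (SSETracer-style axis traces). A PDB
  pseudo-atom dialect (one chain per stick) is also accepted.
* **Correspondence TSV** — ``a_index<TAB>c_index[<TAB>score]`` with 1-based
  indices; used both for native (ground-truth) mappings and predictions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

# altloc characters accepted when extracting the single-conformer Cα trace
_ALTLOC_KEEP = ("\x00", "", " ", "A")


@dataclass
class SSERecordA:
    """One annotated SSE of an atomic model: kind, residue range, Cα trace."""

    chain_id: str
    kind: str  # "helix" | "strand"
    residue_range: tuple[int, int]
    ca_coords: np.ndarray  # (k, 3) Å, residue order
    label: str = ""

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ValueError("ca_coords must be (k, 3)")
        if self.ca_coords.shape[0] < 2:
            raise ValueError("SSE record needs at least 2 Cα coordinates")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError("non-finite Cα coordinate")
        if self.residue_range[1] < self.residue_range[0]:
            raise ValueError("residue range must be nondecreasing")


@dataclass
class SSERecordC:
    """One detected map-side stick: ordered central-axis points in Å."""

    stick_id: int
    axis_points: np.ndarray  # (k, 3)

    def __post_init__(self) -> None:
        self.axis_points = np.asarray(self.axis_points, dtype=float)
        if self.axis_points.ndim != 2 or self.axis_points.shape[1] != 3:
            raise ValueError("axis_points must be (k, 3)")
        if self.axis_points.shape[0] < 2:
            raise ValueError(f"stick {self.stick_id} has fewer than 2 axis points")
        if not np.all(np.isfinite(self.axis_points)):
            raise ValueError(f"stick {self.stick_id} has a non-finite coordinate")


@dataclass(frozen=True)
class NativeCorrespondence:
    """Ground-truth injective partial mapping between A and C indices.

    Not necessarily a bijection: detectors miss real SSEs and hallucinate
    spurious sticks, so indices on either side may be unmatched.
    """

    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        a_seen: set[int] = set()
        c_seen: set[int] = set()
        for a, c in self.pairs:
            if a < 1 or c < 1:
                raise ValueError("correspondence indices are 1-based")
            if a in a_seen:
                raise ValueError(f"a_index {a} appears more than once")
            if c in c_seen:
                raise ValueError(f"c_index {c} appears more than once")
            a_seen.add(a)
            c_seen.add(c)

    def partner_of_a(self, a: int) -> int | None:
        for pa, pc in self.pairs:
            if pa == a:
                return pc
        return None

    def as_dict(self) -> dict[int, int]:
        return {a: c for a, c in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# PDB atomic models


def read_pdb_sses(pdb_text: str, chain_id: str) -> list[SSERecordA]:
    """Extract annotated SSEs (HELIX/SHEET records) with their Cα traces.

    Returns one record per HELIX row / SHEET strand on ``chain_id``, in
    annotation order (helices first, then strands, as in the PDB header).
    Records that resolve fewer than 2 Cα atoms are dropped with a warning.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    if not structure.helices and not structure.sheets:
        raise ValueError(
            "PDB file carries no HELIX/SHEET records; supply a model with "
            "secondary-structure annotations"
        )
    if len(structure) == 0:
        raise ValueError("PDB file contains no coordinate model")
    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = ", ".join(ch.name for ch in model)
        raise ValueError(f"chain {chain_id!r} not found (chains present: {available})")

    # single-conformer Cα lookup by residue number
    ca_by_seqid: dict[int, np.ndarray] = {}
    for res in chain:
        for atom in res:
            if atom.name == "CA" and atom.altloc in _ALTLOC_KEEP:
                ca_by_seqid.setdefault(
                    res.seqid.num, np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                )

    annotations: list[tuple[str, int, int]] = []
    for helix in structure.helices:
        if helix.start.chain_name == chain_id:
            annotations.append(
                ("helix", helix.start.res_id.seqid.num, helix.end.res_id.seqid.num)
            )
    for sheet in structure.sheets:
        for strand in sheet.strands:
            if strand.start.chain_name == chain_id:
                annotations.append(
                    ("strand", strand.start.res_id.seqid.num, strand.end.res_id.seqid.num)
                )
    if not annotations:
        raise ValueError(f"no HELIX/SHEET annotation on chain {chain_id!r}")

    records: list[SSERecordA] = []
    for kind, first, last in annotations:
        lo, hi = min(first, last), max(first, last)
        coords = [ca_by_seqid[s] for s in range(lo, hi + 1) if s in ca_by_seqid]
        label = f"{kind} {chain_id}:{first}-{last}"
        if len(coords) < 2:
            logger.warning("dropping %s: fewer than 2 resolvable Cα atoms", label)
            continue
        records.append(
            SSERecordA(
                chain_id=chain_id,
                kind=kind,
                residue_range=(first, last),
                ca_coords=np.array(coords),
                label=label,
            )
        )
    return records


def write_sse_pdb(records: list[SSERecordA]) -> str:
    """Write records as a minimal annotated PDB (poly-Ala Cα trace).

    Residues are renumbered sequentially with a gap between elements so the
    file round-trips through :func:`read_pdb_sses`.
    """
    structure = gemmi.Structure()
    structure.name = "ssematch synthetic model"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    seq_counter: dict[str, int] = {}
    placed: list[tuple[str, str, int, int]] = []  # kind, chain, first, last

    for rec in records:
        ch = chains.get(rec.chain_id)
        if ch is None:
            ch = gemmi.Chain(rec.chain_id)
            chains[rec.chain_id] = ch
            seq_counter[rec.chain_id] = 0
        first_seq = seq_counter[rec.chain_id] + 2  # gap between elements
        for k, xyz in enumerate(rec.ca_coords):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(first_seq + k, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, xyz))
            res.add_atom(atom)
            ch.add_residue(res)
        last_seq = first_seq + len(rec.ca_coords) - 1
        seq_counter[rec.chain_id] = last_seq
        placed.append((rec.kind, rec.chain_id, first_seq, last_seq))

    for ch in chains.values():
        model.add_chain(ch)
    structure.add_model(model)

    sheet = gemmi.Sheet("A")
    for kind, chain_id, first, last in placed:
        start = gemmi.AtomAddress(chain_id, gemmi.SeqId(first, " "), "ALA", "CA")
        end = gemmi.AtomAddress(chain_id, gemmi.SeqId(last, " "), "ALA", "CA")
        if kind == "helix":
            helix = gemmi.Helix()
            helix.start = start
            helix.end = end
            helix.length = last - first + 1
            structure.helices.append(helix)
        else:
            strand = gemmi.Sheet.Strand()
            strand.start = start
            strand.end = end
            strand.name = str(len(sheet.strands) + 1)
            sheet.strands.append(strand)
    if sheet.strands:
        structure.sheets.append(sheet)
    structure.setup_entities()
    return structure.make_pdb_string()


# ---------------------------------------------------------------------------
# Stick traces


def read_stick_file(text: str) -> list[SSERecordC]:
    """Parse the plain-text stick dialect: blocks of ``x y z`` lines.

    Blank lines separate sticks; ``#`` lines are comments. Sticks are
    numbered 1..n in file order.
    """
    sticks: list[SSERecordC] = []
    block: list[np.ndarray] = []
    block_start_line = 0

    def flush() -> None:
        if not block:
            return
        if len(block) < 2:
            raise ValueError(
                f"stick starting at line {block_start_line} has fewer than 2 axis points"
            )
        sticks.append(SSERecordC(stick_id=len(sticks) + 1, axis_points=np.array(block)))
        block.clear()

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#"):
            continue
        if not line:
            flush()
            continue
        tokens = line.split()
        if len(tokens) != 3:
            raise ValueError(f"line {lineno}: expected 3 coordinates, got {len(tokens)}")
        try:
            point = np.array([float(t) for t in tokens])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric coordinate token") from exc
        if not block:
            block_start_line = lineno
        block.append(point)
    flush()
    return sticks


def write_stick_file(records: list[SSERecordC]) -> str:
    lines = ["# ssematch stick trace file: x y z per axis point, blank line between sticks"]
    for rec in records:
        lines.append("")
        for point in rec.axis_points:
            lines.append("{:.4f} {:.4f} {:.4f}".format(*point))
    return "\n".join(lines) + "\n"


def read_stick_pdb(pdb_text: str) -> list[SSERecordC]:
    """Secondary stick reader: PDB pseudo-atom traces, one chain per stick."""
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise ValueError("PDB stick file contains no coordinate model")
    sticks: list[SSERecordC] = []
    for chain in structure[0]:
        points = [
            np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            for res in chain
            for atom in res
        ]
        if len(points) < 2:
            raise ValueError(f"stick chain {chain.name!r} has fewer than 2 points")
        sticks.append(SSERecordC(stick_id=len(sticks) + 1, axis_points=np.array(points)))
    if not sticks:
        raise ValueError("PDB stick file contains no chains")
    return sticks


# ---------------------------------------------------------------------------
# Correspondence files


def read_correspondence(text: str) -> NativeCorrespondence:
    """Parse a correspondence TSV (``a_index  c_index  [score]``)."""
    pairs: set[tuple[int, int]] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise ValueError(f"line {lineno}: expected 'a_index c_index [score]'")
        try:
            a, c = int(tokens[0]), int(tokens[1])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: indices must be integers") from exc
        pairs.add((a, c))
    return NativeCorrespondence(frozenset(pairs))  # injectivity checked on construction


def write_correspondence(correspondence) -> str:
    """Serialize a correspondence (predicted set or native mapping) as TSV.

    Predicted sets carry a per-pair score column; native mappings do not.
    """
    lines = ["# a_index\tc_index\tscore"]
    if isinstance(correspondence, NativeCorrespondence):
        for a, c in sorted(correspondence.pairs):
            lines.append(f"{a}\t{c}")
    else:
        for a, c, score in sorted(correspondence.pairs):
            lines.append(f"{a}\t{c}\t{score:.6g}")
    return "\n".join(lines) + "\n"
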