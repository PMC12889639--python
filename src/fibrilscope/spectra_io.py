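"""Domain types and readers/writers for shifts, peaks, spectra and structures.

Conventions used package-wide:

* coordinates in Angstrom, chemical shifts in ppm;
* 2D spectra are row-major with ``axis1`` the indirect dimension (omega-1),
  matching Sparky display; ppm decreases with increasing index on default
  grids (NMR display convention), encoded as a negative ``step_ppm``;
* the robust noise floor is 1.4826 x the median absolute deviation of all
  intensities, which tolerates the sparse strong peaks typical of these
  spectra.
"""

from __future__ import annotations

import json
import math

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np


class FormatError(ValueError):
    """A file could not be parsed in the declared dialect."""


# one/three-letter residue codes for the 20 standard amino acids
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: plausible shift windows per nucleus, ppm
SHIFT_RANGES = {"13C": (0.0, 220.0), "15N": (90.0, 150.0)}


def _one_letter(residue_type: str) -> str:
    code = residue_type.strip().upper()
    if len(code) == 3 and code in THREE_TO_ONE:
        return THREE_TO_ONE[code]
    if len(code) == 1 and code in ONE_TO_THREE:
        return code
    raise ValueError(f"unknown residue type {residue_type!r}")


@dataclass(frozen=True)
class Resonance:
    """One assigned chemical shift: residue, atom, nucleus, ppm."""

    residue_number: int
    residue_type: str  # canonical one-letter code
    atom_name: str
    nucleus: str  # "13C" or "15N"
    shift: float


class ResonanceList:
    """Per-atom chemical shifts for the rigid fibril core.

    Enforces (residue_number, atom_name) uniqueness, per-nucleus shift
    windows and basic residue/atom consistency (no CB for glycine).
    """

    def __init__(self, entries: Iterable[Resonance]):
        entries = list(entries)
        if not entries:
            raise ValueError("resonance list is empty")
        index: dict[tuple[int, str], Resonance] = {}
        for e in entries:
            key = (e.residue_number, e.atom_name)
            if key in index:
                raise ValueError(f"duplicate resonance for residue {e.residue_number} atom {e.atom_name}")
            if e.nucleus not in SHIFT_RANGES:
                raise ValueError(f"unsupported nucleus {e.nucleus!r} (expected 13C or 15N)")
            lo, hi = SHIFT_RANGES[e.nucleus]
            if not (lo <= e.shift <= hi):
                raise ValueError(
                    f"shift {e.shift} ppm for {e.residue_type}{e.residue_number} {e.atom_name} "
                    f"outside the {e.nucleus} window [{lo}, {hi}] ppm"
                )
            if e.residue_type == "G" and e.atom_name.upper() == "CB":
                raise ValueError(f"glycine {e.residue_number} cannot carry a CB shift")
            index[key] = e
        self.entries = entries
        self._index = index

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, residue_number: int, atom_name: str) -> Resonance | None:
        return self._index.get((residue_number, atom_name))

    def by_nucleus(self, nucleus: str) -> list[Resonance]:
        return [e for e in self.entries if e.nucleus == nucleus]

    def residue_numbers(self) -> list[int]:
        return sorted({e.residue_number for e in self.entries})


@dataclass(frozen=True)
class Axis:
    """One spectral axis: nucleus label, ppm grid origin, signed step, length."""

    nucleus: str
    first_ppm: float
    step_ppm: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"axis needs >= 2 points, got {self.n}")
        if self.step_ppm == 0 or not math.isfinite(self.step_ppm):
            raise ValueError("axis step must be nonzero and finite (strictly monotone ppm)")

    def ppm(self) -> np.ndarray:
        return self.first_ppm + self.step_ppm * np.arange(self.n)

    @property
    def last_ppm(self) -> float:
        return self.first_ppm + self.step_ppm * (self.n - 1)

    def window(self) -> tuple[float, float]:
        """(low, high) ppm covered by this axis."""
        a, b = self.first_ppm, self.last_ppm
        return (a, b) if a <= b else (b, a)


class Spectrum2D:
    """A gridded 2D intensity image with ppm axis metadata."""

    def __init__(self, axis1: Axis, axis2: Axis, intensity: np.ndarray,
                 noise_floor: float | None = None, id: str | None = None):
        intensity = np.asarray(intensity, dtype=float)
        if intensity.shape != (axis1.n, axis2.n):
            raise ValueError(
                f"intensity shape {intensity.shape} does not match axes ({axis1.n}, {axis2.n})"
            )
        if not np.all(np.isfinite(intensity)):
            raise ValueError("spectrum intensities must all be finite")
        self.axis1 = axis1
        self.axis2 = axis2
        self.intensity = intensity
        self.noise_floor = noise_floor
        self.id = id

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Spectrum2D)
            and self.axis1 == other.axis1
            and self.axis2 == other.axis2
            and np.array_equal(self.intensity, other.intensity)
        )


@dataclass(frozen=True)
class Peak:
    positions: tuple[float, ...]  # ppm per dimension
    intensity: float
    id: str


class PeakList:
    """Picked peak positions (2D or 3D) with intensities."""

    def __init__(self, dimensionality: int, peaks: Iterable[Peak],
                 nuclei: tuple[str, ...] | None = None):
        if dimensionality not in (2, 3):
            raise ValueError("peak lists are 2D or 3D")
        peaks = list(peaks)
        for p in peaks:
            if len(p.positions) != dimensionality:
                raise ValueError(f"peak {p.id} has {len(p.positions)} positions, expected {dimensionality}")
            if not math.isfinite(p.intensity) or not all(math.isfinite(x) for x in p.positions):
                raise ValueError(f"peak {p.id} has non-finite position or intensity")
        if nuclei is not None and len(nuclei) != dimensionality:
            raise ValueError("one nucleus label per dimension")
        self.dimensionality = dimensionality
        self.peaks = peaks
        self.nuclei = nuclei

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass
class AtomRecord:
    name: str
    element: str
    pos: np.ndarray  # xyz, Angstrom


@dataclass
class ResidueRecord:
    number: int
    type: str  # one-letter code; "X" for nonstandard
    atoms: dict[str, AtomRecord] = field(default_factory=dict)


@dataclass
class ChainRecord:
    id: str
    residues: dict[int, ResidueRecord] = field(default_factory=dict)

    def sequence(self) -> str:
        return "".join(self.residues[n].type for n in sorted(self.residues))


@dataclass
class StructureModel:
    chains: dict[str, ChainRecord] = field(default_factory=dict)
    label: str = ""

    def chain_ids(self) -> list[str]:
        return list(self.chains)


class ProtomerEnsemble:
    """One or more models of symmetric fibril chains, residue-indexed."""

    def __init__(self, models: Sequence[StructureModel], symmetry_note: int | None = None):
        models = list(models)
        if not models:
            raise ValueError("ensemble has no models")
        for m in models:
            for ch in m.chains.values():
                for res in ch.residues.values():
                    if len({a.name for a in res.atoms.values()}) != len(res.atoms):
                        raise ValueError(f"duplicate atom names in residue {res.number} chain {ch.id}")
        self.models = models
        self.symmetry_note = symmetry_note if symmetry_note is not None else len(models[0].chains)

    def __len__(self) -> int:
        return len(self.models)


# ---------------------------------------------------------------------------
# resonance readers / writers


def read_resonances(path: str | Path, dialect: str = "tsv") -> ResonanceList:
    """Read a resonance list in the named dialect (``tsv`` or ``nmrstar``).

    The TSV dialect is whitespace-delimited columns
    ``residue_number residue_type atom_name nucleus shift``; lines starting
    with ``#`` are comments.  The NMR-STAR reader handles the standard
    ``Atom_chem_shift`` loop only.  Unparseable rows raise a
    :class:`FormatError` naming the line rather than being silently dropped.
    """
    path = Path(path)
    if dialect == "tsv":
        entries = _read_resonances_tsv(path)
    elif dialect == "nmrstar":
        entries = _read_resonances_star(path)
    else:
        raise ValueError(f"unknown resonance dialect {dialect!r}")
    if not entries:
        raise FormatError(f"{path}: no assigned 13C/15N resonances found")
    return ResonanceList(entries)


def _read_resonances_tsv(path: Path) -> list[Resonance]:
    entries = []
    bad: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        try:
            if len(parts) != 5:
                raise ValueError(f"expected 5 columns, got {len(parts)}")
            num, rtype, atom, nucleus, shift = parts
            entries.append(
                Resonance(int(num), _one_letter(rtype), atom.upper(), nucleus, float(shift))
            )
        except ValueError as exc:
            bad.append(f"line {lineno}: {exc}")
    if bad:
        raise FormatError(f"{path}: " + "; ".join(bad))
    return entries


def _read_resonances_star(path: Path) -> list[Resonance]:
    """Minimal NMR-STAR v3 reader for the Atom_chem_shift loop."""
    lines = path.read_text().splitlines()
    entries: list[Resonance] = []
    i = 0
    n = len(lines)
    while i < n:
        if lines[i].strip() != "loop_":
            i += 1
            continue
        # collect tag block
        tags: list[str] = []
        i += 1
        while i < n and lines[i].strip().startswith("_"):
            tags.append(lines[i].strip())
            i += 1
        if not any(t.startswith("_Atom_chem_shift.") for t in tags):
            # skip to stop_ of this loop
            while i < n and lines[i].strip() != "stop_":
                i += 1
            continue
        cols = {t.split(".", 1)[1]: k for k, t in enumerate(tags)}

        def col(*names):
            for nm in names:
                if nm in cols:
                    return cols[nm]
            return None

        c_seq = col("Comp_index_ID", "Seq_ID")
        c_comp = col("Comp_ID")
        c_atom = col("Atom_ID")
        c_type = col("Atom_type")
        c_iso = col("Atom_isotope_number")
        c_val = col("Val")
        if c_seq is None or c_comp is None or c_atom is None or c_val is None:
            raise FormatError(f"{path}: Atom_chem_shift loop lacks required tags")
        while i < n:
            row = lines[i].strip()
            i += 1
            if row == "stop_":
                break
            if not row or row.startswith("#"):
                continue
            vals = row.split()
            if len(vals) < len(tags):
                raise FormatError(f"{path}: line {i}: expected {len(tags)} fields, got {len(vals)}")
            atom_type = vals[c_type].upper() if c_type is not None else vals[c_atom][0].upper()
            if atom_type not in ("C", "N"):
                continue
            iso = vals[c_iso] if c_iso is not None else ("13" if atom_type == "C" else "15")
            try:
                entries.append(
                    Resonance(
                        int(vals[c_seq]),
                        _one_letter(vals[c_comp]),
                        vals[c_atom].upper(),
                        f"{iso}{atom_type}",
                        float(vals[c_val]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {i}: {exc}") from exc
    return entries


def write_resonances_tsv(res: ResonanceList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# residue_number residue_type atom_name nucleus shift_ppm\n")
        for e in res.entries:
            fh.write(f"{e.residue_number}\t{e.residue_type}\t{e.atom_name}\t{e.nucleus}\t{e.shift:.3f}\n")


# ---------------------------------------------------------------------------
# spectrum readers / writers


def read_spectrum(path_matrix: str | Path, path_meta: str | Path) -> Spectrum2D:
    """Read a plain-text matrix plus JSON axis metadata.

    Round-trips bit-exactly with :func:`write_spectrum`.
    """
    meta = json.loads(Path(path_meta).read_text())
    ax1 = Axis(**meta["axis1"])
    ax2 = Axis(**meta["axis2"])
    intensity = np.loadtxt(path_matrix, delimiter=",", ndmin=2)
    if intensity.shape != (ax1.n, ax2.n):
        raise FormatError(
            f"matrix shape {intensity.shape} does not match metadata shape ({ax1.n}, {ax2.n})"
        )
    return Spectrum2D(ax1, ax2, intensity,
                      noise_floor=meta.get("noise_floor"), id=meta.get("id"))


def write_spectrum(spec: Spectrum2D, path_matrix: str | Path, path_meta: str | Path) -> None:
    meta = {
        "axis1": {"nucleus": spec.axis1.nucleus, "first_ppm": spec.axis1.first_ppm,
                  "step_ppm": spec.axis1.step_ppm, "n": spec.axis1.n},
        "axis2": {"nucleus": spec.axis2.nucleus, "first_ppm": spec.axis2.first_ppm,
                  "step_ppm": spec.axis2.step_ppm, "n": spec.axis2.n},
    }
    if spec.noise_floor is not None:
        meta["noise_floor"] = spec.noise_floor
    if spec.id is not None:
        meta["id"] = spec.id
    Path(path_meta).write_text(json.dumps(meta, indent=1))
    # %.17g preserves doubles exactly
    np.savetxt(path_matrix, spec.intensity, delimiter=",", fmt="%.17g")


# ---------------------------------------------------------------------------
# peak list readers / writers


def read_peaks(path: str | Path, dimensionality: int = 2,
               nuclei: tuple[str, ...] | None = None) -> PeakList:
    """Read a whitespace-delimited peak list, one peak per line.

    Columns: an optional Sparky-style assignment label (any token that does
    not parse as a number), then one ppm position per dimension, then the
    intensity.  Unassigned peaks get synthetic ids ``pk0001`` ...
    """
    peaks = []
    counter = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        label = None
        try:
            float(parts[0])
        except ValueError:
            label = parts[0]
            parts = parts[1:]
        if len(parts) != dimensionality + 1:
            raise FormatError(
                f"{path}: line {lineno}: expected {dimensionality} positions + intensity"
            )
        try:
            values = [float(x) for x in parts]
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
        counter += 1
        peaks.append(Peak(tuple(values[:-1]), values[-1], label or f"pk{counter:04d}"))
    return PeakList(dimensionality, peaks, nuclei=nuclei)


def write_peaks(peaks: PeakList, path: str | Path) -> None:
    with open(path, "w") as fh:
        dims = " ".join(f"w{i+1}_ppm" for i in range(peaks.dimensionality))
        fh.write(f"# id {dims} intensity\n")
        for p in peaks:
            pos = " ".join(f"{x:.4f}" for x in p.positions)
            fh.write(f"{p.id} {pos} {p.intensity:.6g}\n")


# ---------------------------------------------------------------------------
# structures


def read_structures(paths: str | Path | Sequence[str | Path]) -> ProtomerEnsemble:
    """Read PDB/mmCIF files into a :class:`ProtomerEnsemble`.

    Multi-model files become multiple ensemble members; chain identities are
    preserved.  For altloc groups the highest-occupancy conformer is kept
    (ties broken by file order).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    models: list[StructureModel] = []
    for path in paths:
        st = gemmi.read_structure(str(path))
        st.setup_entities()
        for model in st:
            sm = StructureModel(label=f"{Path(path).stem}/{model.num}")
            for chain in model:
                cr = ChainRecord(id=chain.name)
                for residue in chain:
                    info = gemmi.find_tabulated_residue(residue.name)
                    if info is not None and not info.is_amino_acid():
                        continue
                    one = THREE_TO_ONE.get(residue.name.upper(), "X")
                    rr = ResidueRecord(number=residue.seqid.num, type=one)
                    best: dict[str, gemmi.Atom] = {}
                    for atom in residue:
                        prev = best.get(atom.name)
                        if prev is None or atom.occ > prev.occ:
                            best[atom.name] = atom
                    for name, atom in best.items():
                        rr.atoms[name] = AtomRecord(
                            name=name,
                            element=atom.element.name,
                            pos=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        )
                    if rr.atoms:
                        cr.residues[rr.number] = rr
                if cr.residues:
                    sm.chains[cr.id] = cr
            if sm.chains:
                models.append(sm)
    if not models:
        raise FormatError(f"no models with amino-acid chains found in {list(map(str, paths))}")
    return ProtomerEnsemble(models)


def write_pdb(ens: ProtomerEnsemble, path: str | Path) -> None:
    """Write an ensemble as a (multi-model) PDB file via gemmi."""
    st = gemmi.Structure()
    st.name = "fibrilscope"
    for k, sm in enumerate(ens.models, start=1):
        model = gemmi.Model(k)
        for cid, chain in sm.chains.items():
            gchain = gemmi.Chain(cid)
            for num in sorted(chain.residues):
                res = chain.residues[num]
                gres = gemmi.Residue()
                gres.name = ONE_TO_THREE.get(res.type, "UNK")
                gres.seqid = gemmi.SeqId(num, " ")
                for atom in res.atoms.values():
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element)
                    ga.pos = gemmi.Position(*atom.pos)
                    ga.occ = 1.0
                    gres.add_atom(ga)
                gchain.add_residue(gres)
            model.add_chain(gchain)
        st.add_model(model)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# noise floor


def estimate_noise_floor(spec: Spectrum2D) -> float:
    """Robust noise-level estimate: 1.4826 x MAD of all intensities.

    Peaks occupy a small fraction of cells in these spectra, so the median
    absolute deviation tracks the baseline noise sigma even with strong
    signals present.  Raises for spectra whose MAD is zero (constant or
    all-zero images have no estimable noise floor).
    """
    if spec.intensity.size < 100:
        raise ValueError("noise floor needs >= 100 cells")
    flat = spec.intensity.ravel()
    mad = np.median(np.abs(flat - np.median(flat)))
    sigma = 1.4826 * mad
    if sigma <= 0:
        raise ValueError("noise floor undefined: spectrum has zero median absolute deviation")
    return float(sigma)
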