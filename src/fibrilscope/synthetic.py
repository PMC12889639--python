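"""Seeded generators for every input the pipeline consumes.

The generators emulate the data of a cross-beta amyloid fibril study
without any download: an idealized serpentine protomer fold stacked into a
protofilament with the characteristic 4.7 A inter-protomer rise,
beta-sheet-biased chemical shifts, and noisy simulated spectra and peak
lists.  The default fold template follows the alpha-synuclein rigid core
(residues 33-98) with six beta strands; a second template with re-placed
turns provides a distinct polymorph family for classification-recovery
tests.

Geometry is a CA trace with pseudo-backbone (N, C, O) and pseudo-CB atoms
at fixed local offsets: sufficient for every distance-based operation here,
while full sidechain building stays out of scope.  The random-coil shift
table is a fixture convention, not a scientific claim.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from fibrilscope.spectra_io import (
    AtomRecord,
    ChainRecord,
    Peak,
    PeakList,
    ProtomerEnsemble,
    Resonance,
    ResonanceList,
    ResidueRecord,
    Spectrum2D,
    StructureModel,
)
from fibrilscope.spectrum_sim import ExperimentSpec, enumerate_cross_peaks, render_spectrum

#: human alpha-synuclein, 140 residues
ASYN_SEQUENCE = (
    "MDVFMKGLSKAKEGVVAAAEKTKQGVAEAAGKTKEGVLYV"
    "GSKTKEGVVHGVATVAEKTKEQVTNVGGAVVTGVTAVAQK"
    "TVEGAGSIAAATGFVKKDQLGKNEEGAPQEGILEDMPVDP"
    "DNEAYEMPSEEGYQDYEPEA"
)

#: rigid-core strand layout used by the default template (six beta strands)
DEFAULT_STRANDS = [(39, 41), (43, 58), (60, 66), (69, 79), (81, 84), (90, 97)]

#: random-coil shift conventions per residue type (ppm); "C" is the carbonyl
RANDOM_COIL = {
    "A": {"CA": 52.5, "CB": 19.1, "C": 177.8, "N": 123.8},
    "R": {"CA": 56.0, "CB": 30.9, "C": 176.3, "N": 120.5},
    "N": {"CA": 53.1, "CB": 38.9, "C": 175.2, "N": 118.7},
    "D": {"CA": 54.2, "CB": 41.1, "C": 176.3, "N": 120.4},
    "C": {"CA": 58.2, "CB": 28.0, "C": 174.6, "N": 118.8},
    "Q": {"CA": 55.7, "CB": 29.4, "C": 176.0, "N": 119.8},
    "E": {"CA": 56.6, "CB": 29.9, "C": 176.6, "N": 120.2, "CD": 183.0},
    "G": {"CA": 45.1, "C": 174.9, "N": 108.8},
    "H": {"CA": 55.0, "CB": 29.0, "C": 174.1, "N": 118.2},
    "I": {"CA": 61.1, "CB": 38.8, "C": 176.4, "N": 119.9},
    "L": {"CA": 55.1, "CB": 42.4, "C": 177.6, "N": 121.8},
    "K": {"CA": 56.2, "CB": 33.1, "C": 176.6, "N": 120.4, "CE": 41.9},
    "M": {"CA": 55.4, "CB": 32.9, "C": 176.3, "N": 119.6},
    "F": {"CA": 57.7, "CB": 39.6, "C": 175.8, "N": 120.3},
    "P": {"CA": 63.3, "CB": 32.1, "C": 177.3, "N": 136.0},
    "S": {"CA": 58.3, "CB": 63.8, "C": 174.6, "N": 115.7},
    "T": {"CA": 61.8, "CB": 69.8, "C": 174.7, "N": 113.6, "CG2": 21.5},
    "W": {"CA": 57.5, "CB": 29.6, "C": 176.1, "N": 121.3},
    "Y": {"CA": 57.9, "CB": 38.8, "C": 175.9, "N": 120.3},
    "V": {"CA": 62.2, "CB": 32.9, "C": 176.3, "N": 119.2, "CG1": 21.1},
}

#: beta-strand secondary shift offsets, ppm
BETA_OFFSET = {"CA": -2.0, "CB": +2.0}

CA_CA_STEP = 3.8  # A, along a strand
# Inter-sheet spacing of the serpentine fold.  Deliberately compressed to the
# tight end of steric-zipper packing so that the CA-CA contact map at the
# conventional 6 A cutoff carries the fold topology, as it does in real
# fibril cores where mated sheets interdigitate.
SHEET_SPACING = 5.8


@dataclass(frozen=True)
class FoldTemplate:
    """Recipe for one idealized serpentine fibril fold."""

    sequence: str = ASYN_SEQUENCE[32:98]  # residues 33..98
    first_residue: int = 33
    strand_segments: tuple[tuple[int, int], ...] = tuple(DEFAULT_STRANDS)
    turn_geometry: tuple[int, ...] = ()  # +1/-1 per turn; empty = all +1
    rise: float = 4.7
    twist: float = 0.0  # degrees per protomer
    n_protomers: int = 5
    jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.n_protomers < 1:
            raise ValueError("need at least one protomer")
        last = self.first_residue + len(self.sequence) - 1
        prev_end = None
        for s, e in self.strand_segments:
            if s > e or s < self.first_residue or e > last:
                raise ValueError(f"strand segment ({s}, {e}) outside sequence {self.first_residue}-{last}")
            if prev_end is not None and s <= prev_end:
                raise ValueError("strand segments must be non-overlapping and ascending")
            prev_end = e

    @property
    def last_residue(self) -> int:
        return self.first_residue + len(self.sequence) - 1

    def residue_type(self, number: int) -> str:
        return self.sequence[number - self.first_residue]

    def strand_index(self, number: int) -> int | None:
        for k, (s, e) in enumerate(self.strand_segments):
            if s <= number <= e:
                return k
        return None

    def turn_sign(self, k: int) -> int:
        if k < len(self.turn_geometry):
            return self.turn_geometry[k]
        return 1


def default_template(**overrides) -> FoldTemplate:
    return replace(FoldTemplate(), **overrides) if overrides else FoldTemplate()


def _ca_trace(t: FoldTemplate) -> dict[int, np.ndarray]:
    """Serpentine in-plane CA trace: strands at 3.8 A spacing, hairpin turns."""
    pos: dict[int, np.ndarray] = {}
    strands = list(t.strand_segments)
    # leading residues before the first strand run as an extension of it
    x = 0.0
    y = 0.0
    for k, (s, e) in enumerate(strands):
        direction = 1.0 if k % 2 == 0 else -1.0
        if k == 0:
            # place the first strand, plus any leading tail, along +x
            start = t.first_residue
            for num in range(start, e + 1):
                pos[num] = np.array([x, y, 0.0])
                if num < e:
                    x += direction * CA_CA_STEP
            continue
        ps, pe = strands[k - 1]
        sign = t.turn_sign(k - 1)
        y_new = y + sign * SHEET_SPACING
        # loop residues pe+1 .. s-1 sit on a semicircular arc bulging outward
        loop = list(range(pe + 1, s))
        centre = np.array([x, (y + y_new) / 2.0, 0.0])
        radius = SHEET_SPACING / 2.0
        bulge = 1.0 if (k - 1) % 2 == 0 else -1.0
        for m, num in enumerate(loop, start=1):
            theta = np.pi * m / (len(loop) + 1)
            pos[num] = centre + np.array(
                [bulge * radius * np.sin(theta), -sign * radius * np.cos(theta), 0.0]
            )
        y = y_new
        for num in range(s, e + 1):
            pos[num] = np.array([x, y, 0.0])
            if num < e:
                x += direction * CA_CA_STEP
    # trailing residues after the last strand
    last_s, last_e = strands[-1]
    direction = 1.0 if (len(strands) - 1) % 2 == 0 else -1.0
    for num in range(last_e + 1, t.last_residue + 1):
        x += direction * CA_CA_STEP
        pos[num] = np.array([x, y, 0.0])
    return pos


def make_fibril(t: FoldTemplate) -> ProtomerEnsemble:
    """Build a stacked idealized fibril from a fold template.

    Protomer copies are stacked along z at the template rise (optionally
    twisted about the fibril axis); seeded Gaussian jitter is applied per
    atom after stacking, so protomers fluctuate independently.
    """
    ca = _ca_trace(t)
    numbers = sorted(ca)
    zhat = np.array([0.0, 0.0, 1.0])
    protomer: list[tuple[int, str, dict[str, np.ndarray]]] = []
    for i, num in enumerate(numbers):
        rtype = t.residue_type(num)
        here = ca[num]
        nxt = ca[numbers[i + 1]] if i + 1 < len(numbers) else None
        prv = ca[numbers[i - 1]] if i > 0 else None
        u = (nxt - here) if nxt is not None else (here - prv)
        u = u / np.linalg.norm(u)
        v = np.cross(u, zhat)
        pleat = 1.0 if i % 2 == 0 else -1.0
        atoms = {
            "CA": here,
            "N": here - 1.0 * u + 0.7 * v,
            "C": here + 1.0 * u + 0.7 * v,
            "O": here + 1.2 * u + 1.9 * v,
        }
        if rtype != "G":
            # pleated CB points into the inter-sheet gap (steric zipper)
            atoms["CB"] = here + pleat * 1.5 * v
            # pseudo sidechain tips for residues whose shifts carry them
            tip = {"E": "CD", "K": "CE", "T": "CG2", "V": "CG1"}.get(rtype)
            if tip:
                atoms[tip] = atoms["CB"] + 1.3 * zhat
        protomer.append((num, rtype, atoms))

    rng = np.random.default_rng(t.seed)
    model = StructureModel(label="synthetic_fibril")
    for p in range(t.n_protomers):
        angle = np.deg2rad(t.twist * p)
        rot = np.array(
            [[np.cos(angle), -np.sin(angle), 0.0],
             [np.sin(angle), np.cos(angle), 0.0],
             [0.0, 0.0, 1.0]]
        )
        shift = np.array([0.0, 0.0, t.rise * p])
        chain = ChainRecord(id=chr(ord("A") + p))
        for num, rtype, atoms in protomer:
            rr = ResidueRecord(number=num, type=rtype)
            for name, xyz in atoms.items():
                pos = rot @ xyz + shift
                if t.jitter_sigma > 0:
                    pos = pos + rng.normal(0.0, t.jitter_sigma, 3)
                element = "N" if name == "N" else ("O" if name == "O" else "C")
                rr.atoms[name] = AtomRecord(name=name, element=element, pos=pos)
            chain.residues[num] = rr
        model.chains[chain.id] = chain
    return ProtomerEnsemble([model], symmetry_note=t.n_protomers)


def topology_seed(t: FoldTemplate) -> int:
    """Deterministic seed derived from the fold topology (not the jitter seed)."""
    import zlib

    key = str((t.first_residue, t.sequence, t.strand_segments, t.turn_geometry))
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def make_resonances(t: FoldTemplate, noise_ppm: float = 0.1,
                    seed: int | None = None,
                    packing_ppm: float = 1.0) -> ResonanceList:
    """Beta-sheet-biased shift list for a template.

    Random-coil base shifts per residue type, CA -2 / CB +2 ppm offsets
    inside strand segments, a fold-specific packing perturbation
    (``packing_ppm``) emulating the tertiary-environment shift differences
    that distinguish polymorphs, and per-atom scatter (``noise_ppm``).
    Proline keeps its characteristic backbone 15N near 136 ppm (no amide
    proton); glutamate carries its carboxyl CD near 183 ppm.

    The default random seed derives from the fold topology, so templates
    differing only in jitter seed share an identical shift list (chemical
    shifts are determined by the fold), while different topologies draw
    independent packing environments.
    """
    rng = np.random.default_rng(topology_seed(t) if seed is None else seed)
    entries = []
    for num in range(t.first_residue, t.last_residue + 1):
        rtype = t.residue_type(num)
        base = RANDOM_COIL.get(rtype)
        if base is None:
            continue
        in_strand = t.strand_index(num) is not None
        for atom, shift in base.items():
            if in_strand and atom in BETA_OFFSET:
                shift = shift + BETA_OFFSET[atom]
            if packing_ppm > 0:
                shift = shift + rng.normal(0.0, packing_ppm)
            if noise_ppm > 0:
                shift = shift + rng.normal(0.0, noise_ppm)
            nucleus = "15N" if atom == "N" else "13C"
            entries.append(Resonance(num, rtype, atom, nucleus, float(shift)))
    return ResonanceList(entries)


def make_noisy_spectrum(ens: ProtomerEnsemble, res: ResonanceList,
                        exp: ExperimentSpec, snr: float, seed: int,
                        grid=None, id: str | None = None) -> Spectrum2D:
    """Simulated spectrum plus seeded Gaussian noise.

    The noise sigma is the maximum peak amplitude divided by ``snr``, in the
    amplitude (integral) units of the peak list.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    peaks = enumerate_cross_peaks(ens, res, exp)
    clean = render_spectrum(peaks, exp, grid=grid)
    rng = np.random.default_rng(seed)
    amp_max = max((abs(p.intensity) for p in peaks), default=0.0)
    sigma = amp_max / snr
    noisy = clean.intensity + rng.normal(0.0, sigma, clean.intensity.shape)
    return Spectrum2D(clean.axis1, clean.axis2, noisy, id=id)


def perturb_peaks(peaks: PeakList, pos_sigma: float = 0.05, snr: float = 10.0,
                  seed: int = 0) -> PeakList:
    """Add measurement noise to a peak list.

    Positions get Gaussian jitter of ``pos_sigma`` ppm per dimension;
    intensities get Gaussian noise with sigma = max intensity / snr.
    """
    rng = np.random.default_rng(seed)
    imax = max((abs(p.intensity) for p in peaks), default=0.0)
    sigma_i = imax / snr
    out = []
    for p in peaks:
        pos = tuple(x + rng.normal(0.0, pos_sigma) for x in p.positions)
        out.append(Peak(pos, p.intensity + rng.normal(0.0, sigma_i), p.id))
    return PeakList(peaks.dimensionality, out, nuclei=peaks.nuclei)


def make_fold_pair() -> tuple[FoldTemplate, FoldTemplate]:
    """Two templates sharing sequence but with re-placed turns.

    Fold B re-segments the strand layout (five strands instead of six, all
    turns moved), guaranteeing a distinct long-range contact map and
    distinct beta-biased shifts for the re-assigned residues.
    """
    a = default_template()
    b = replace(
        a,
        strand_segments=((35, 44), (47, 57), (59, 70), (73, 83), (86, 96)),
    )
    return a, b


def contact_map(ens: ProtomerEnsemble, cutoff: float = 6.0,
                min_separation: int = 2) -> set[tuple[int, int]]:
    """Intra-chain CA-CA contact pairs of the middle chain."""
    model = ens.models[0]
    chain = list(model.chains.values())[len(model.chains) // 2]
    nums = sorted(chain.residues)
    coords = np.array([chain.residues[n].atoms["CA"].pos for n in nums])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    pairs = set()
    for i in range(len(nums)):
        for j in range(i + min_separation, len(nums)):
            if d[i, j] <= cutoff:
                pairs.add((nums[i], nums[j]))
    return pairs
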