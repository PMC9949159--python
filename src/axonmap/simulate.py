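"""Ground-truthed synthetic datasets for the barcode-sequencing pipeline.

The generator emulates a barcoded cortical injection read out by cyclic
in situ sequencing: neurons of four projection classes (CT, ET, ITi, ITc)
carry random nucleotide barcodes and deposit rolonies along class-specific
trajectories.  Each rolony is observed once per sequencing cycle as a dot in
one of four channels (one per nucleotide), subject to per-cycle dropout,
per-base substitution errors and positional jitter.  Two contaminant
processes of real data are modelled explicitly: *floating* rolonies that
detach from a soma during processing and settle broadly on the soma section
(± 1 section), and *secondary-infection* barcodes appearing as compact
glial-like rolony clusters in target regions.

All positions are in μm in a right-handed frame — x: mediolateral (midline
at ``SimConfig.midline_x``, ipsilateral = larger x), y: dorsoventral
(increasing ventrally), z: anteroposterior.  Sections are cut along z at
``section_thickness`` μm.  Dot tables carry pixel coordinates
(``x_um / pixel_size``) so that downstream modules see the same units as
detections from real images.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ALPHABET = "GTAC"  # channel 1..4 = G, T, A, C
CLASSES = ("CT", "ET", "ITi", "ITc")

# Default anatomical boxes (μm).  The layout mimics a unilateral auditory-
# cortex injection imaged over a ~1.1 mm anteroposterior span: ipsi- and
# contralateral cortical fields, thalamus, striatum, midbrain, and the
# striatal-thalamic fiber region where CT and ET axons travel in separate
# dorsal/ventral bundles.
DEFAULT_REGIONS: dict[str, tuple[tuple[float, float], ...]] = {
    "AudI": ((8000.0, 10000.0), (500.0, 2500.0), (6400.0, 7000.0)),
    "VisI": ((8000.0, 10000.0), (500.0, 2500.0), (7000.0, 7520.0)),
    "AudC": ((1400.0, 3400.0), (500.0, 2500.0), (6400.0, 7000.0)),
    "VisC": ((1400.0, 3400.0), (500.0, 2500.0), (7000.0, 7520.0)),
    "Thal": ((6000.0, 8000.0), (3500.0, 5500.0), (6750.0, 7500.0)),
    "Str": ((8200.0, 9800.0), (2600.0, 4600.0), (6400.0, 6740.0)),
    "SupCol": ((6200.0, 7800.0), (1000.0, 2500.0), (7380.0, 7520.0)),
    "Fiber": ((8250.0, 9000.0), (3500.0, 5000.0), (6750.0, 7500.0)),
}

CONTRA_REGIONS = frozenset({"AudC", "VisC"})

# Fraction of a neuron's rolonies deposited in each region, by class.
CLASS_REGION_WEIGHTS: dict[str, dict[str, float]] = {
    "CT": {"Thal": 0.45, "Fiber": 0.25, "AudI": 0.30},
    "ET": {"Thal": 0.30, "Fiber": 0.25, "SupCol": 0.20, "Str": 0.15, "AudI": 0.10},
    "ITi": {"AudI": 0.45, "VisI": 0.30, "Str": 0.25},
    "ITc": {"AudI": 0.30, "VisI": 0.20, "AudC": 0.30, "VisC": 0.10, "Str": 0.10},
}

# Soma depth (fraction of cortical depth) by class: CT somata sit in deep
# layer 6 (~90%), ET in layer 5 (~60%), IT cells span the upper layers.
CLASS_SOMA_DEPTH: dict[str, tuple[float, float]] = {
    "CT": (0.90, 0.04),
    "ET": (0.60, 0.05),
    "ITi": (0.35, 0.12),
    "ITc": (0.45, 0.15),
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Acquisition constants (17 cycles, 0.55 μm pixels, 20 μm sections, fixed
    barcode positions 9–10) follow the imaging protocol the pipeline was
    designed for; noise rates are chosen to stress the pipeline rather than
    to match any particular experiment.
    """

    n_neurons: int = 200
    barcode_length: int = 17
    fixed_positions: tuple[int, ...] = (9, 10)  # 1-based
    fixed_letters: str = "GG"
    n_cycles: int = 17
    pixel_size: float = 0.55  # μm / pixel
    section_thickness: float = 20.0  # μm
    n_sections: int = 56
    z_origin: float = 6400.0  # μm, anterior face of section 0
    midline_x: float = 5700.0
    dropout_rate: float = 0.10  # per rolony per cycle
    substitution_rate: float = 0.01  # per base-call
    jitter_sd: float = 0.5  # pixels
    n_floating_per_soma: int = 12
    floating_radius: float = 800.0  # μm tangential scatter of floaters
    n_secondary_barcodes: int = 3
    class_mixture: tuple[float, float, float, float] = (0.12, 0.08, 0.45, 0.35)
    n_rolonies_per_neuron: int = 40
    fiber_bundle_overlap: float = 0.10  # fractional y-overlap of CT/ET bundles
    injection_center: tuple[float, float] = (9000.0, 6700.0)  # (x, z) in AudI
    injection_spread: float = 200.0  # μm, soma scatter around the center
    regions: Mapping[str, tuple[tuple[float, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (
            ("dropout_rate", self.dropout_rate),
            ("substitution_rate", self.substitution_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if abs(sum(self.class_mixture) - 1.0) > 1e-9 or min(self.class_mixture) < 0:
            raise ValueError("class_mixture must be nonnegative and sum to 1")
        if self.fixed_positions and self.barcode_length <= max(self.fixed_positions) - 1:
            raise ValueError("barcode_length must exceed max(fixed_positions)")
        if len(self.fixed_letters) != len(self.fixed_positions):
            raise ValueError("fixed_letters must match fixed_positions in length")

    @property
    def n_variable(self) -> int:
        return self.barcode_length - len(self.fixed_positions)

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class GroundTruthNeuron:
    """One barcoded neuron with its class, soma and rolony cloud."""

    neuron_id: int
    barcode: str
    cell_class: str  # CT | ET | ITi | ITc
    soma_xyz: tuple[float, float, float]
    soma_depth: float  # fraction of cortical depth in [0, 1]
    soma_section: int
    rolonies: pd.DataFrame  # columns: x, y, z, section, region, is_floating
    trajectory_tag: str  # dorsal | ventral | none


def generate_barcode_library(
    n: int, cfg: SimConfig, rng: np.random.Generator | None = None
) -> list[str]:
    """Draw ``n`` random barcodes uniformly over the variable positions.

    Fixed positions (library design constants) carry ``cfg.fixed_letters`` in
    every barcode.  A 30-nt random region has ~4^30 ≈ 1e18 possible
    sequences; even the 15 variable positions used here give 4^15 ≈ 1e9,
    so collisions and 1-Hamming neighbours are rare at realistic library
    sizes (see :func:`axonmap.codebook.one_neighbor_probability`).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    fixed0 = [p - 1 for p in cfg.fixed_positions]
    letters = np.array(list(ALPHABET))
    draws = rng.integers(0, 4, size=(n, cfg.barcode_length))
    chars = letters[draws]
    for idx, letter in zip(fixed0, cfg.fixed_letters):
        chars[:, idx] = letter
    return ["".join(row) for row in chars]


def _uniform_in_box(
    rng: np.random.Generator, box: Sequence[tuple[float, float]], n: int
) -> np.ndarray:
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    return rng.uniform(lo, hi, size=(n, 3))


def _section_of(z: np.ndarray, cfg: SimConfig) -> np.ndarray:
    s = np.floor((np.asarray(z) - cfg.z_origin) / cfg.section_thickness).astype(int)
    return np.clip(s, 0, cfg.n_sections - 1)


def _cortical_y(depth: np.ndarray, ybox: tuple[float, float]) -> np.ndarray:
    """Map depth fraction (0 = pia) onto the dorsoventral extent of a box."""
    return ybox[0] + np.clip(depth, 0.0, 1.0) * (ybox[1] - ybox[0])


def _fiber_strata(cfg: SimConfig) -> dict[str, tuple[float, float]]:
    """Gaussian y-bands for the dorsal (CT) and ventral (ET) fiber bundles.

    Bundle centers sit at the quarter points of the fiber box's y-extent;
    the bundle width (SD of a cell's bundle position) is set so the two
    ±2σ envelopes overlap by ``fiber_bundle_overlap`` of their extent —
    two distinct fascicles with a narrow mixing zone, as in the coronal
    view of corticothalamic vs extratelencephalic axon tracts.
    Returns {class: (center, sigma)}.
    """
    y0, y1 = cfg.regions["Fiber"][1]
    span = y1 - y0
    c_ct = y0 + 0.25 * span
    c_et = y0 + 0.75 * span
    sep = c_et - c_ct
    sigma = sep / (4.0 * max(1.0 - cfg.fiber_bundle_overlap, 1e-6))
    return {"CT": (c_ct, sigma), "ET": (c_et, sigma)}


def _sample_region_cloud(
    rng: np.random.Generator,
    region: str,
    n: int,
    cfg: SimConfig,
    cell_class: str,
    tangential_center: np.ndarray,
    tangential_sigma: float,
    fiber_y: float | None,
    thal_center: np.ndarray | None,
) -> np.ndarray:
    """Sample ``n`` rolony positions in one region for one cell."""
    box = cfg.regions[region]
    if region == "Fiber":
        # Axons of one cell travel as a tight bundle at a fixed y.
        pts = _uniform_in_box(rng, box, n)
        pts[:, 1] = np.clip(fiber_y + rng.normal(0, 30.0, n), box[1][0], box[1][1])
        return pts
    if region == "Thal" and thal_center is not None:
        pts = thal_center + rng.normal(0, 150.0, size=(n, 3))
        for ax in range(3):
            pts[:, ax] = np.clip(pts[:, ax], box[ax][0], box[ax][1])
        return pts
    if region in ("AudI", "VisI", "AudC", "VisC"):
        # Cortical target: cell-specific tangential locus + laminar profile.
        # Arbors are compact along the sectioning axis (~±75 μm), as real
        # terminal arbors are, rather than smeared across the whole area.
        depth_mu, depth_sd = {
            "CT": (0.85, 0.10),
            "ET": (0.55, 0.15),
            "ITi": (0.30, 0.15),
            "ITc": (0.50, 0.20),
        }[cell_class]
        x = tangential_center[0] + rng.normal(0, tangential_sigma, n)
        if region == "AudI":
            # local collaterals stay near the soma
            zc = float(np.clip(tangential_center[1], box[2][0] + 75, box[2][1] - 75))
        else:
            # long-range target: arbor locus anywhere within the area
            zc = rng.uniform(box[2][0] + 75, box[2][1] - 75)
        z = zc + rng.normal(0, 75.0, n)
        if region in CONTRA_REGIONS:
            x = 2 * cfg.midline_x - x  # mirror into the other hemisphere
        x = np.clip(x, box[0][0], box[0][1])
        z = np.clip(z, box[2][0], box[2][1])
        y = _cortical_y(rng.normal(depth_mu, depth_sd, n), box[1])
        return np.column_stack([x, y, z])
    # subcortical target (striatum, midbrain): one compact arbor per cell
    center = _uniform_in_box(rng, box, 1)[0]
    pts = center + rng.normal(0, 100.0, size=(n, 3))
    for ax in range(3):
        pts[:, ax] = np.clip(pts[:, ax], box[ax][0], box[ax][1])
    return pts


def simulate_neurons(cfg: SimConfig, rng: np.random.Generator | None = None) -> list[GroundTruthNeuron]:
    """Generate the ground-truth neuron population.

    Class geometry: CT and ET cells send thalamic projections through
    distinct dorsal/ventral strata of the fiber box; IT cells arborize in
    ipsilateral (ITi) or both (ITc, ≥ 5 contralateral rolonies) cortices.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    barcodes = generate_barcode_library(cfg.n_neurons, cfg, rng)
    classes = rng.choice(len(CLASSES), size=cfg.n_neurons, p=list(cfg.class_mixture))
    strata = _fiber_strata(cfg)
    aud_box = cfg.regions["AudI"]
    thal_box = cfg.regions["Thal"]
    thal_ymid = 0.5 * (thal_box[1][0] + thal_box[1][1])

    neurons: list[GroundTruthNeuron] = []
    for i in range(cfg.n_neurons):
        cls = CLASSES[classes[i]]
        cx, cz = cfg.injection_center
        sx = np.clip(cx + rng.normal(0, cfg.injection_spread), aud_box[0][0], aud_box[0][1])
        sz = np.clip(cz + rng.normal(0, cfg.injection_spread), aud_box[2][0], aud_box[2][1])
        mu, sd = CLASS_SOMA_DEPTH[cls]
        depth = float(np.clip(rng.normal(mu, sd), 0.02, 0.98))
        sy = float(_cortical_y(np.array([depth]), aud_box[1])[0])
        section = int(_section_of(np.array([sz]), cfg)[0])

        weights = CLASS_REGION_WEIGHTS[cls]
        counts = rng.multinomial(cfg.n_rolonies_per_neuron, list(weights.values()))
        if cls == "ITc":  # the class definition requires >= 5 contralateral
            ci = list(weights).index("AudC")
            while counts[ci] < 5:
                j = int(np.argmax(counts))
                counts[j] -= 1
                counts[ci] += 1
        fiber_y = None
        if cls in strata:
            center, sigma = strata[cls]
            ylo, yhi = cfg.regions["Fiber"][1]
            fiber_y = float(np.clip(rng.normal(center, sigma), ylo, yhi))
        thal_center = None
        if cls in ("CT", "ET"):
            # CT axons terminate dorsally in thalamus, ET ventrally, with
            # partial intermixing mirroring higher-order/first-order targets.
            tc = _uniform_in_box(rng, thal_box, 1)[0]
            off = -400.0 if cls == "CT" else 400.0
            tc[1] = np.clip(thal_ymid + off + rng.normal(0, 150.0), thal_box[1][0], thal_box[1][1])
            thal_center = tc
        tangential_center = np.array([sx, sz]) + rng.normal(0, 300.0, 2)
        tangential_sigma = rng.choice([120.0, 400.0])  # focal vs diffuse arbors

        frames = []
        for region, n_r in zip(weights, counts):
            if n_r == 0:
                continue
            pts = _sample_region_cloud(
                rng, region, int(n_r), cfg, cls, tangential_center,
                tangential_sigma, fiber_y, thal_center,
            )
            frames.append(pd.DataFrame({
                "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2], "region": region,
            }))
        rol = pd.concat(frames, ignore_index=True)
        rol["section"] = _section_of(rol["z"].to_numpy(), cfg)
        rol["is_floating"] = False

        # Floating rolonies: detached during processing, they settle with a
        # broad tangential scatter, mostly on the soma section with some
        # spillover to its neighbours.
        if cfg.n_floating_per_soma > 0:
            nf = cfg.n_floating_per_soma
            theta = rng.uniform(0, 2 * math.pi, nf)
            # uniform radial draw biases outward -> wide, sparse scatter
            r = cfg.floating_radius * rng.uniform(0.2, 1.0, nf)
            fx = np.clip(sx + r * np.cos(theta), aud_box[0][0], aud_box[0][1])
            fz_sec = section + rng.choice([-1, 0, 1], size=nf, p=[0.2, 0.6, 0.2])
            fz_sec = np.clip(fz_sec, 0, cfg.n_sections - 1)
            fz = cfg.z_origin + (fz_sec + 0.5) * cfg.section_thickness
            fy = np.clip(sy + r * np.sin(theta), aud_box[1][0], aud_box[1][1])
            flo = pd.DataFrame({
                "x": fx, "y": fy, "z": fz, "region": "AudI",
                "section": fz_sec.astype(int), "is_floating": True,
            })
            rol = pd.concat([rol, flo], ignore_index=True)

        tag = {"CT": "dorsal", "ET": "ventral"}.get(cls, "none")
        neurons.append(GroundTruthNeuron(
            neuron_id=i, barcode=barcodes[i], cell_class=cls,
            soma_xyz=(float(sx), float(sy), float(sz)), soma_depth=depth,
            soma_section=section, rolonies=rol, trajectory_tag=tag,
        ))
    return neurons


def _secondary_clusters(cfg: SimConfig, rng: np.random.Generator) -> tuple[list[str], pd.DataFrame]:
    """Compact glial-like rolony clusters from secondary infection in target
    regions (never the injection region)."""
    if cfg.n_secondary_barcodes == 0:
        return [], pd.DataFrame(columns=["x", "y", "z", "region", "section", "is_floating"])
    barcodes = generate_barcode_library(cfg.n_secondary_barcodes, cfg, rng)
    target_regions = [r for r in cfg.regions if r not in ("AudI", "Fiber")]
    frames = []
    for b_i in range(cfg.n_secondary_barcodes):
        region = target_regions[int(rng.integers(len(target_regions)))]
        box = cfg.regions[region]
        center = _uniform_in_box(rng, box, 1)[0]
        n_r = int(rng.integers(20, 40))
        pts = center + rng.normal(0, 30.0, size=(n_r, 3))
        for ax in range(3):
            pts[:, ax] = np.clip(pts[:, ax], box[ax][0], box[ax][1])
        frames.append(pd.DataFrame({
            "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2], "region": region,
            "barcode_index": b_i,
        }))
    df = pd.concat(frames, ignore_index=True)
    df["section"] = _section_of(df["z"].to_numpy(), cfg)
    df["is_floating"] = False
    return barcodes, df


LETTER_TO_CHANNEL = {c: i + 1 for i, c in enumerate(ALPHABET)}


def emit_dot_observations(
    neurons: Sequence[GroundTruthNeuron],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observe every rolony across sequencing cycles as dot calls.

    Returns ``(dots, rolony_truth)``.  ``dots`` has one row per detected dot
    with pixel coordinates in the section frame and the ground-truth linkage
    columns ``rolony_id``/``neuron_id`` (``neuron_id = -1`` for secondary-
    infection contaminants); the pipeline itself never reads the linkage —
    it exists for auditing.  Per cycle, a rolony yields at most one dot
    (none when dropped); the observed channel equals the barcode letter
    except with probability ``substitution_rate``; positions are jittered by
    ``jitter_sd`` pixels.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    sec_barcodes, sec_rol = _secondary_clusters(cfg, rng)

    rol_rows = []
    rid = 0
    for nrn in neurons:
        for _, r in nrn.rolonies.iterrows():
            rol_rows.append((
                rid, nrn.neuron_id, nrn.barcode, r.x, r.y, r.z, int(r.section),
                r.region, bool(r.is_floating), False,
            ))
            rid += 1
    for _, r in sec_rol.iterrows():
        rol_rows.append((
            rid, -1, sec_barcodes[int(r.barcode_index)], r.x, r.y, r.z,
            int(r.section), r.region, False, True,
        ))
        rid += 1
    truth = pd.DataFrame(rol_rows, columns=[
        "rolony_id", "neuron_id", "barcode", "x", "y", "z", "section",
        "region", "is_floating", "is_secondary",
    ])

    n_rol = len(truth)
    n_cyc = cfg.n_cycles
    bc_idx = np.zeros((n_rol, n_cyc), dtype=np.int8)
    for i, b in enumerate(truth["barcode"].to_numpy()):
        bc_idx[i] = [LETTER_TO_CHANNEL[c] for c in b[:n_cyc]]

    keep = rng.random((n_rol, n_cyc)) >= cfg.dropout_rate
    sub = rng.random((n_rol, n_cyc)) < cfg.substitution_rate
    # substitution: shift to one of the three other channels
    shift = rng.integers(1, 4, size=(n_rol, n_cyc))
    channels = np.where(sub, (bc_idx - 1 + shift) % 4 + 1, bc_idx)

    px = truth["x"].to_numpy() / cfg.pixel_size
    py = truth["y"].to_numpy() / cfg.pixel_size
    jx = rng.normal(0, cfg.jitter_sd, size=(n_rol, n_cyc)) if cfg.jitter_sd > 0 else np.zeros((n_rol, n_cyc))
    jy = rng.normal(0, cfg.jitter_sd, size=(n_rol, n_cyc)) if cfg.jitter_sd > 0 else np.zeros((n_rol, n_cyc))
    inten = rng.lognormal(math.log(500.0), 0.3, size=(n_rol, n_cyc))

    rol_ids, cycles = np.nonzero(keep)
    dots = pd.DataFrame({
        "cycle": cycles + 1,
        "tile": truth["section"].to_numpy()[rol_ids],
        "x": px[rol_ids] + jx[rol_ids, cycles],
        "y": py[rol_ids] + jy[rol_ids, cycles],
        "channel": channels[rol_ids, cycles],
        "intensity": inten[rol_ids, cycles],
        "rolony_id": truth["rolony_id"].to_numpy()[rol_ids],
        "neuron_id": truth["neuron_id"].to_numpy()[rol_ids],
        "is_floating": truth["is_floating"].to_numpy()[rol_ids],
        "is_secondary": truth["is_secondary"].to_numpy()[rol_ids],
    })
    dots.insert(0, "dot_id", np.arange(len(dots)))
    return dots, truth


def render_image_stack(
    dots: pd.DataFrame,
    shape: tuple[int, int],
    n_planes: int = 5,
    sigma_xy: float = 1.0,
    sigma_z: float = 0.9,
    noise_sd: float = 0.0,
    bleed: np.ndarray | None = None,
    illumination_gradient: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render dots of one tile/cycle into a 4-channel z-stack.

    Each dot becomes a Gaussian blob (3–7 px across at typical sigma) whose
    z-profile peaks on a contiguous slab of planes.  ``bleed`` is an
    optional 4×4 channel-mixing matrix (columns = true channel); additive
    Gaussian noise and a linear illumination gradient along x are optional.
    Returns an array of shape ``(4, n_planes, H, W)``.
    """
    H, W = shape
    if rng is None:
        rng = np.random.default_rng(0)
    stack = np.zeros((4, n_planes, H, W), dtype=np.float64)
    yy, xx = np.mgrid[0:H, 0:W]
    zc_all = dots["z_plane"].to_numpy() if "z_plane" in dots else np.full(len(dots), (n_planes - 1) / 2)
    zz = np.arange(n_planes)
    for (_, d), zc in zip(dots.iterrows(), zc_all):
        blob = np.exp(-(((xx - d.x) ** 2 + (yy - d.y) ** 2) / (2 * sigma_xy**2)))
        zprof = np.exp(-((zz - zc) ** 2) / (2 * sigma_z**2))
        stack[int(d.channel) - 1] += d.intensity * zprof[:, None, None] * blob[None]
    if bleed is not None:
        stack = np.einsum("ij,jzyx->izyx", np.asarray(bleed, float), stack)
    if illumination_gradient:
        ramp = 1.0 + illumination_gradient * (xx / max(W - 1, 1))
        stack *= ramp[None, None]
    if noise_sd > 0:
        stack += rng.normal(0, noise_sd, size=stack.shape)
    return np.clip(stack, 0, None)


@dataclass
class SimulatedDataset:
    cfg: SimConfig
    neurons: list[GroundTruthNeuron]
    dots: pd.DataFrame
    rolony_truth: pd.DataFrame

    @property
    def barcodes(self) -> list[str]:
        return [n.barcode for n in self.neurons]


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """End-to-end convenience: neurons + dot observations from one seed."""
    rng = np.random.default_rng(cfg.seed)
    neurons = simulate_neurons(cfg, rng)
    dots, truth = emit_dot_observations(neurons, cfg, rng)
    return SimulatedDataset(cfg=cfg, neurons=neurons, dots=dots, rolony_truth=truth)


def write_dot_table(dots: pd.DataFrame, path) -> None:
    """Write a dot table as TSV (documented header, one row per dot)."""
    dots.to_csv(path, sep="\t", index=False)


def read_dot_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
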