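"""Synthetic inputs with known ground truth for every pipeline stage.

Generators: glycan-strand populations digested into muropeptide quant
tables, centroided LC-MS runs from a quant table, paired phase/fluorescence
cell images with configurable localization patterns (polar foci migrating
to a medial septal band as cells widen), and Bocillin-FL titration lane
tables. Every generator is deterministic under a fixed seed and emits its
ground truth alongside the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import murolib
from .cells import capsule_volume
from .lcms import CentroidedRun
from .pgfeatures import OligomerAbundance


# ---------------------------------------------------------------------------
# glycan strands and muropeptide digests
# ---------------------------------------------------------------------------


@dataclass
class StrandPopulation:
    """Glycan strand lengths (disaccharide units); one anhydro terminus each."""

    lengths: np.ndarray
    seed: int

    @property
    def n_strands(self) -> int:
        return int(self.lengths.size)

    @property
    def n_units(self) -> int:
        return int(self.lengths.sum())

    @property
    def mean_length(self) -> float:
        return float(self.lengths.mean())


def gen_strands(n_strands: int, mean_length: float, seed: int = 0) -> StrandPopulation:
    """Draw strand lengths from a geometric distribution with the given mean.

    The geometric law (support >= 1, memoryless termination) is the simplest
    model consistent with exactly one anhydro terminus per strand.
    """
    if mean_length <= 1:
        raise ValueError("mean_length must exceed 1 disaccharide unit")
    rng = np.random.default_rng(seed)
    lengths = rng.geometric(1.0 / mean_length, size=n_strands)
    return StrandPopulation(lengths=lengths, seed=seed)


@dataclass
class DigestTruth:
    """Directly counted ground truth emitted with a synthetic digest."""

    abundance: OligomerAbundance  # realized species-based percentages
    crosslinks_per_100: float  # crosslinked bonds per 100 species
    anhydro_unit_pct: float  # anhydro units per 100 disaccharide units
    mean_chain_length: float  # total units / strands
    n_species: int
    n_units: int


def digest_strands(
    pop: StrandPopulation,
    oligomer_probs: Sequence[float] = (1.0, 0.0, 0.0, 0.0),
    stem_length: int = 4,
) -> tuple[pd.DataFrame, DigestTruth]:
    """Digest a strand population into muropeptide species.

    Disaccharide units are grouped into oligomer species (a species of order
    o consumes o units) drawn with the given probabilities; the one anhydro
    terminus per strand is assigned to units uniformly at random. The quant
    table's molar percentages are the realized species counts, so downstream
    statistics can be checked against the truth exactly.
    """
    probs = np.asarray(oligomer_probs, dtype=float)
    if probs.shape != (4,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("oligomer_probs must be 4 non-negative values summing to 1")
    rng = np.random.default_rng([pop.seed, 1])
    n_units = pop.n_units
    # draw species orders until the unit budget is exhausted
    orders: list[int] = []
    remaining = n_units
    batch = max(16, int(n_units / max(probs @ np.arange(1, 5), 1.0) * 1.2))
    while remaining > 0:
        draws = rng.choice(np.arange(1, 5), size=batch, p=probs)
        for o in draws:
            if o > remaining:
                continue  # fill the tail with whatever still fits
            orders.append(int(o))
            remaining -= int(o)
            if remaining == 0:
                break
        if remaining > 0 and probs[0] == 0 and remaining < int(np.argmax(probs > 0)) + 1:
            # cannot fit any allowed order: emit monomers for the tail
            orders.extend([1] * remaining)
            remaining = 0
    orders_arr = np.array(orders)
    n_species = orders_arr.size
    # uniform assignment of the n_strands anhydro units over all units
    cum = np.cumsum(orders_arr)
    anh_units = rng.choice(n_units, size=pop.n_strands, replace=False)
    species_of_unit = np.searchsorted(cum, anh_units, side="right")
    anh_per_species = np.bincount(species_of_unit, minlength=n_species)
    # tabulate species by (order, n_anhydro)
    counts: dict[tuple[int, int], int] = {}
    for o, a in zip(orders_arr, anh_per_species):
        counts[(int(o), int(a))] = counts.get((int(o), int(a)), 0) + 1
    rows = []
    for (o, a), cnt in sorted(counts.items()):
        name = murolib.ORDER_LETTER[o] + str(stem_length) * o + "N" * a
        rows.append({"name": name, "area": float(cnt), "molar_percent": 100.0 * cnt / n_species})
    quant = pd.DataFrame(rows).sort_values("name", ignore_index=True)
    order_counts = np.bincount(orders_arr, minlength=5)
    anhydro_species = int(np.count_nonzero(anh_per_species))
    truth = DigestTruth(
        abundance=OligomerAbundance(
            monomers_pct=100.0 * order_counts[1] / n_species,
            dimers_pct=100.0 * order_counts[2] / n_species,
            trimers_pct=100.0 * order_counts[3] / n_species,
            tetramers_pct=100.0 * order_counts[4] / n_species,
            anhydro_pct=100.0 * anhydro_species / n_species,
        ),
        crosslinks_per_100=100.0 * float(((orders_arr - 1)).sum()) / n_species,
        anhydro_unit_pct=100.0 * pop.n_strands / n_units,
        mean_chain_length=n_units / pop.n_strands,
        n_species=n_species,
        n_units=n_units,
    )
    return quant, truth


def library_for_quant(
    quant: pd.DataFrame, stem_length: int = 4
) -> list[murolib.MuropeptideRecord]:
    """Records for every species name appearing in a synthetic quant table."""
    return [
        murolib.make_record(murolib.parse_name(name)) for name in quant["name"]
    ]


# ---------------------------------------------------------------------------
# centroided LC-MS runs
# ---------------------------------------------------------------------------


def gen_lcms_run(
    quant: pd.DataFrame,
    library: Sequence[murolib.MuropeptideRecord],
    ppm_noise_sd: float = 5.0,
    peak_cv: float = 0.05,
    rt_assignment: dict[str, float] | None = None,
    seed: int = 0,
    run_length_min: float = 18.0,
    scan_interval_s: float = 0.25,
    peak_sigma_min: float = 0.04,
    area_scale: float = 1e4,
    n_noise_peaks: int = 0,
) -> tuple[CentroidedRun, dict[str, float]]:
    """Render a centroided run from target molar percentages.

    Each species elutes as a Gaussian peak at its assigned retention time,
    sampled at the scan interval; centroid m/z values carry multiplicative
    per-scan ppm noise and peak heights a multiplicative per-scan CV (which
    averages out over the ~tens of scans per peak, so integrated areas stay
    proportional to molar percentages). Returns the run and the retention
    times actually used (ground truth).
    """
    rng = np.random.default_rng(seed)
    by_name = {r.name: r for r in library}
    missing = [n for n in quant["name"] if n not in by_name]
    if missing:
        raise KeyError(f"quant species missing from library: {missing}")
    times = np.arange(0.0, run_length_min, scan_interval_s / 60.0)
    names = list(quant["name"])
    if rt_assignment is None:
        assigned = np.linspace(1.5, run_length_min - 2.0, num=len(names))
        rt_assignment = dict(zip(sorted(names), assigned))
    rts = np.array([rt_assignment[n] for n in names])
    order = np.argsort(rts)
    if np.any(np.diff(rts[order]) < peak_sigma_min):
        warnings.warn("assigned retention times collide within one peak width")
    scan_idx_parts, mz_parts, int_parts = [], [], []
    for name, rt in zip(names, rts):
        record = by_name[name]
        target = record.mz_by_charge[1]
        pct = float(quant.loc[quant["name"] == name, "molar_percent"].iloc[0])
        area = area_scale * pct
        amp = area / (peak_sigma_min * np.sqrt(2.0 * np.pi))
        y = amp * np.exp(-0.5 * ((times - rt) / peak_sigma_min) ** 2)
        keep = y > amp * 1e-4
        idx = np.flatnonzero(keep)
        if peak_cv > 0:
            y_idx = y[idx] * np.clip(1.0 + rng.normal(0.0, peak_cv, size=idx.size), 0.0, None)
        else:
            y_idx = y[idx]
        eps = rng.normal(0.0, ppm_noise_sd * 1e-6, size=idx.size)
        scan_idx_parts.append(idx)
        mz_parts.append(target * (1.0 + eps))
        int_parts.append(y_idx)
    if n_noise_peaks:
        idx = rng.integers(0, times.size, size=n_noise_peaks)
        scan_idx_parts.append(idx)
        mz_parts.append(rng.uniform(100.0, 2000.0, size=n_noise_peaks))
        int_parts.append(rng.uniform(0.0, area_scale * 0.01, size=n_noise_peaks))
    if not scan_idx_parts:
        raise ValueError("quant table is empty")
    run = CentroidedRun.from_arrays(
        times,
        np.concatenate(scan_idx_parts),
        np.concatenate(mz_parts),
        np.concatenate(int_parts),
    )
    return run, dict(zip(names, rts))


# ---------------------------------------------------------------------------
# synthetic cell image pairs
# ---------------------------------------------------------------------------


@dataclass
class LocalizationModel:
    """How fluorescence is laid out inside a synthetic cell.

    ``polar_foci``: two Gaussian foci at the pole centers. ``septal_accumulation``:
    a medial band across the short axis. ``mixed``: a width-dependent blend,
    shifting weight from the poles to the septum as the cell widens between
    ``mixed_w_lo`` and ``mixed_w_hi`` (um) — emulating the polar-to-medial
    migration over the division cycle. Fluorophore density is per unit cell
    volume, so total signal scales with the capsule volume.
    """

    pattern: Literal["polar_foci", "septal_accumulation", "mixed"] = "mixed"
    focus_sd_um: float = 0.15
    septal_sd_um: float = 0.15
    density: float = 2000.0  # a.u. per um^3
    background_level: float = 100.0
    noise_sd: float = 5.0
    mixed_w_lo: float = 1.0
    mixed_w_hi: float = 1.3
    phase_background: float = 3000.0
    phase_cell: float = 1200.0
    phase_noise_sd: float = 30.0

    def septal_weight(self, width_um: float) -> float:
        if self.pattern == "polar_foci":
            return 0.0
        if self.pattern == "septal_accumulation":
            return 1.0
        return float(
            np.clip((width_um - self.mixed_w_lo) / (self.mixed_w_hi - self.mixed_w_lo), 0.0, 1.0)
        )


@dataclass
class SyntheticImagePair:
    phase: np.ndarray  # uint16
    fluor: np.ndarray  # uint16
    truth: pd.DataFrame
    pixel_size_um: float

    def save(self, outdir) -> None:
        import tifffile
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(out / "phase.tif", self.phase)
        tifffile.imwrite(out / "fluor.tif", self.fluor)
        self.truth.to_csv(out / "truth.csv", index=False)


def gen_cell_images(
    n_cells: int,
    width_range_um: tuple[float, float] = (0.66, 1.50),
    length_range_um: tuple[float, float] = (2.0, 2.4),
    model: LocalizationModel | None = None,
    pixel_size_um: float = 0.05,
    image_shape: tuple[int, int] | None = None,
    seed: int = 0,
    max_retries: int = 200,
) -> SyntheticImagePair:
    """Render capsule-shaped cells at random poses into a phase/fluor pair.

    Cells are placed by rejection sampling without overlap; fluorescence is
    the localization-model field masked to the cell interior and scaled so
    the integrated signal equals density x capsule volume. The truth table
    lists per-cell pose, dimensions, volume, total signal and septal weight.

    Cell widths are drawn with a linearly decreasing density over
    ``width_range_um`` (a Beta(1,2) shape): in an age-structured dividing
    population young (thin) cells outnumber deeply constricting (wide)
    ones, so the thinnest 60% of the population ends near the lower third
    of the width range, as observed for width-grouped demographs.
    """
    model = model or LocalizationModel()
    rng = np.random.default_rng(seed)
    l_max = length_range_um[1]
    if image_shape is None:
        side_um = max(np.sqrt(max(n_cells, 1) * (l_max + 0.6) ** 2 * 2.2), 4 * l_max)
        side = int(np.ceil(side_um / pixel_size_um))
        image_shape = (side, side)
    phase = np.full(image_shape, model.phase_background, dtype=float)
    fluor = np.zeros(image_shape, dtype=float)
    margin = l_max / 2 + 0.5
    lo = margin / pixel_size_um
    hi_r = image_shape[0] - lo
    hi_c = image_shape[1] - lo
    if n_cells > 0 and (hi_r <= lo or hi_c <= lo):
        raise ValueError("image too small for requested cells")
    centers: list[tuple[float, float]] = []
    rows = []
    for i in range(n_cells):
        placed = False
        for _ in range(max_retries):
            w = width_range_um[0] + (width_range_um[1] - width_range_um[0]) * (
                1.0 - np.sqrt(rng.uniform())
            )
            l = rng.uniform(*length_range_um)
            theta = rng.uniform(0.0, np.pi)
            cr = rng.uniform(lo, hi_r)
            cc = rng.uniform(lo, hi_c)
            min_d = (l + l_max) / 2.0 / pixel_size_um + 0.2 / pixel_size_um
            if all((cr - r0) ** 2 + (cc - c0) ** 2 > min_d**2 for r0, c0 in centers):
                placed = True
                break
        if not placed:
            raise RuntimeError(f"could not place cell {i + 1} without overlap")
        centers.append((cr, cc))
        vol = capsule_volume(l, w)
        total_signal = model.density * vol
        ws = model.septal_weight(w)
        _render_cell(phase, fluor, model, pixel_size_um, cr, cc, theta, l, w, total_signal, ws)
        rows.append(
            {
                "cell": i + 1,
                "center_row_px": cr,
                "center_col_px": cc,
                "angle_rad": theta,
                "length_um": l,
                "width_um": w,
                "volume_um3": vol,
                "total_signal": total_signal,
                "septal_weight": ws,
            }
        )
    phase += rng.normal(0.0, model.phase_noise_sd, size=image_shape)
    fluor += model.background_level + rng.normal(0.0, model.noise_sd, size=image_shape)
    phase_u = np.clip(np.round(phase), 0, 65535).astype(np.uint16)
    fluor_u = np.clip(np.round(fluor), 0, 65535).astype(np.uint16)
    truth = pd.DataFrame(
        rows,
        columns=[
            "cell", "center_row_px", "center_col_px", "angle_rad", "length_um",
            "width_um", "volume_um3", "total_signal", "septal_weight",
        ],
    )
    return SyntheticImagePair(phase_u, fluor_u, truth, pixel_size_um)


def _render_cell(
    phase: np.ndarray,
    fluor: np.ndarray,
    model: LocalizationModel,
    ps: float,
    cr: float,
    cc: float,
    theta: float,
    length: float,
    width: float,
    total_signal: float,
    septal_weight: float,
) -> None:
    half_px = int(np.ceil((length / 2.0 + 2 * ps) / ps)) + 1
    r0 = max(int(cr) - half_px, 0)
    r1 = min(int(cr) + half_px + 1, phase.shape[0])
    c0 = max(int(cc) - half_px, 0)
    c1 = min(int(cc) + half_px + 1, phase.shape[1])
    rr, cc_grid = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    dy = (rr - cr) * ps
    dx = (cc_grid - cc) * ps
    u = np.array([np.cos(theta), np.sin(theta)])  # long axis (row, col) direction
    t = dy * u[0] + dx * u[1]
    s = -dy * u[1] + dx * u[0]
    a = max((length - width) / 2.0, 0.0)
    tc = np.clip(t, -a, a)
    dist2 = (t - tc) ** 2 + s**2
    inside = dist2 <= (width / 2.0) ** 2
    if not np.any(inside):
        return
    phase[r0:r1, c0:c1][inside] = model.phase_cell
    sf = model.focus_sd_um
    polar = np.exp(-0.5 * (((t + a) ** 2 + s**2) / sf**2)) + np.exp(
        -0.5 * (((t - a) ** 2 + s**2) / sf**2)
    )
    septal = np.exp(-0.5 * (t / model.septal_sd_um) ** 2)
    field = (1.0 - septal_weight) * polar + septal_weight * septal
    field = np.where(inside, field, 0.0)
    total = field.sum()
    if total <= 0:
        return
    fluor[r0:r1, c0:c1] += field * (total_signal / total)


# ---------------------------------------------------------------------------
# titration lane tables
# ---------------------------------------------------------------------------


def gen_titration(
    antibiotic: str = "drugA",
    concentrations: Sequence[float] | None = None,
    ic50: float = 1.0,
    hill: float = 1.0,
    enhancement: bool = False,
    amplitude: float = 0.5,
    half_max_conc: float | None = None,
    replicates: int = 2,
    noise_cv: float = 0.05,
    control_intensity: float = 1e4,
    unit: str = "uM",
    seed: int = 0,
) -> pd.DataFrame:
    """Lane table for a log-logistic inhibition or saturable enhancement curve.

    Inhibitory response: ``1 / (1 + (c/ic50)^hill)``. Enhancement:
    ``1 + amplitude * c / (c + K)``. Multiplicative noise applies to every
    lane, controls included; the default seven concentrations span four
    decades around the IC50 (or K).
    """
    rng = np.random.default_rng(seed)
    if enhancement:
        K = half_max_conc if half_max_conc is not None else 1.0
        center = K
    else:
        if ic50 <= 0:
            raise ValueError("ic50 must be positive for an inhibitory curve")
        center = ic50
    if concentrations is None:
        concentrations = center * np.logspace(-2, 2, 7)
    rows = []
    for rep in range(1, replicates + 1):
        for c in [0.0, *concentrations]:
            if enhancement:
                rel = 1.0 + amplitude * c / (c + (half_max_conc or 1.0))
            else:
                rel = 1.0 / (1.0 + (c / ic50) ** hill) if c > 0 else 1.0
            noise = 1.0 + rng.normal(0.0, noise_cv) if noise_cv > 0 else 1.0
            rows.append(
                {
                    "antibiotic": antibiotic,
                    "concentration": c,
                    "unit": unit,
                    "replicate": rep,
                    "intensity": max(control_intensity * rel * noise, 0.0),
                }
            )
    return pd.DataFrame(rows)
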