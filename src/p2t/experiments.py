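"""Scaled end-to-end phantom studies (desk-scale figure reproductions).

These drivers wire the full chain together: fixture phantom -> beam plan ->
acquisition -> reconstruction -> corrections -> contrast statistics.  They
run at desk scale (1e6-1e7 primaries on one CPU) rather than the
10^10-primary scale of a full distributed Monte Carlo study; statistical
claims are therefore checked through the corresponding scaled tolerances.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import analysis, recon
from .beams import Beam, BeamPlan, fan_beam_plan, pair_weighted_fluence_map
from .detection import RingDetector
from .image import Image
from .materials import (ELEMENTS, NANOPARTICLE_LAYOUT, VoxelPhantom,
                        insert_layout, nanoparticle_phantom)
from .simulate import Acquisition, run_acquisition

__all__ = ["nanoparticle_study", "partial_view_study", "partial_view_plan",
           "dose_monitoring_study", "NanoparticleStudy"]

ROI_RADIUS = 1.2   # cm, central sub-region of each 1.75 cm insert
WATER_SLOTS = ("water", "water_b", "water_c")
SPB_RING = RingDetector(time_resolution_ns=0.3)
TOF_RING = RingDetector(time_resolution_ns=0.02)

#: the three bottom inserts imaged in the partial-view study (left to right)
PARTIAL_VIEW_INSERTS = ("I", "Yb", "Bi")


@dataclass
class NanoparticleStudy:
    phantom: VoxelPhantom
    plan_spbe: BeamPlan
    plan_ve: BeamPlan
    acq_spbe: Acquisition
    acq_ve: Acquisition
    fluence: object
    images: dict[str, Image]
    contrasts: dict[str, dict[str, float]]
    regressions: dict[str, tuple[float, float, float]]
    config: dict = field(default_factory=dict)


def _high_z_slots() -> dict[str, int]:
    return {s: ELEMENTS[s].Z for s in NANOPARTICLE_LAYOUT if s in ELEMENTS}


def nanoparticle_study(seed: int, total_primaries: float = 1e7,
                       phantom: VoxelPhantom | None = None) -> NanoparticleStudy:
    """High-Z linearity study: 20 fan beams, SPBE + VE acquisitions.

    The SPBE acquisition (300 ps detector) feeds the SPB reconstruction;
    the VE acquisition (20 ps detector) feeds TOF and FBP.  Both use half
    of ``total_primaries``.  All images are attenuation- and
    fluence-corrected and normalised to the water insert.
    """
    rng = np.random.default_rng(seed)
    phantom = phantom or nanoparticle_phantom()
    plan_spbe = fan_beam_plan(20, mode="SPBE").scaled_to(total_primaries / 2)
    plan_ve = fan_beam_plan(20, mode="VE").scaled_to(total_primaries / 2)

    acq_spbe = run_acquisition(phantom, plan_spbe, SPB_RING, rng.spawn(1)[0])
    acq_ve = run_acquisition(phantom, plan_ve, TOF_RING, rng.spawn(1)[0])

    flu = pair_weighted_fluence_map(plan_ve, phantom)
    gt_pts = np.concatenate([acq_spbe.truth_points, acq_ve.truth_points])
    gt_w = np.concatenate([acq_spbe.truth_weights, acq_ve.truth_weights])
    from .transport import tally_ground_truth
    images = {
        "GT": tally_ground_truth(gt_pts, gt_w, phantom),
        "SPB": recon.spb_reconstruct(acq_spbe.lors, plan_spbe, phantom),
        "TOF": recon.tof_reconstruct(acq_ve.lors, phantom),
        "FBP": recon.fbp(
            recon.attenuation_correct_sinogram(
                recon.rebin_to_sinogram(acq_ve.lors), phantom),
            phantom),
    }
    images = {k: recon.fluence_correct(v, flu) for k, v in images.items()}

    centers = insert_layout("nanoparticle")
    water_c = centers["water"]
    images = {k: analysis.normalize_image(v, water_c, ROI_RADIUS)
              for k, v in images.items()}

    zs = _high_z_slots()
    contrasts: dict[str, dict[str, float]] = {}
    regressions = {}
    for method, img in images.items():
        # pool the three water inserts into the reference (triples the
        # reference statistics without changing its expectation)
        water_ref = float(np.mean([analysis.roi_mean(img, centers[s],
                                                     ROI_RADIUS)
                                   for s in WATER_SLOTS]))
        c = {}
        for slot in zs:
            c[slot] = (analysis.roi_mean(img, centers[slot], ROI_RADIUS)
                       - water_ref) / water_ref
        contrasts[method] = c
        regressions[method] = analysis.linearity_regression(
            [c[s] for s in zs], list(zs.values()))

    return NanoparticleStudy(
        phantom, plan_spbe, plan_ve, acq_spbe, acq_ve, flu, images,
        contrasts, regressions,
        config={"seed": seed, "total_primaries": total_primaries})


# ---------------------------------------------------------------------------
# Partial view
# ---------------------------------------------------------------------------

def partial_view_plan(mode: str, y_band: tuple[float, float] = (-8.6, -3.0),
                      pencil_width: float = 0.2) -> BeamPlan:
    """Two opposing horizontal beams whose pencils cover only a y-band.

    The aperture (the yellow-box region) contains the three bottom inserts;
    voxels outside the band receive zero fluence from every pencil.
    """
    beams = []
    for ang in (0.0, 180.0):
        l_y = np.cos(np.deg2rad(ang))  # lateral = (-sin a, cos a)
        lo, hi = sorted((y_band[0] / l_y, y_band[1] / l_y))
        n = int(np.round((hi - lo) / pencil_width))
        offsets = lo + (np.arange(n) + 0.5) * pencil_width
        beams.append(Beam(angle_deg=ang, mode=mode,
                          pencil_offsets=offsets, pencil_width=pencil_width,
                          fluence=np.ones(n)))
    return BeamPlan(tuple(beams))


def _roi_counts(points: np.ndarray, center, radius) -> int:
    d2 = (points[:, 0] - center[0]) ** 2 + (points[:, 1] - center[1]) ** 2
    return int(np.sum(d2 <= radius ** 2))


def _insert_table(acq_spbe, acq_ve, plan_spbe, phantom, flu):
    """Per-insert (fluence-corrected ROI mean, located-event count) for
    GT, SPB and TOF."""
    from .transport import tally_ground_truth
    centers = insert_layout("nanoparticle")
    gt_pts = np.concatenate([acq_spbe.truth_points, acq_ve.truth_points])
    gt_w = np.concatenate([acq_spbe.truth_weights, acq_ve.truth_weights])
    gt = recon.fluence_correct(tally_ground_truth(gt_pts, gt_w, phantom), flu)
    spb = recon.fluence_correct(
        recon.spb_reconstruct(acq_spbe.lors, plan_spbe, phantom), flu)
    tof = recon.fluence_correct(recon.tof_reconstruct(acq_ve.lors, phantom), flu)
    spb_pts, spb_ok = recon.spb_locate(acq_spbe.lors, plan_spbe)
    tof_pts, _ = recon.tof_locate(acq_ve.lors)
    located = {"GT": gt_pts, "SPB": spb_pts[spb_ok], "TOF": tof_pts}
    images = {"GT": gt, "SPB": spb, "TOF": tof}
    table = {}
    for method in images:
        vals = {}
        counts = {}
        for slot in PARTIAL_VIEW_INSERTS:
            vals[slot] = analysis.roi_mean(images[method], centers[slot],
                                           ROI_RADIUS)
            counts[slot] = _roi_counts(located[method], centers[slot],
                                       ROI_RADIUS)
        mean_val = np.mean(list(vals.values()))
        table[method] = {s: (vals[s] / mean_val, counts[s])
                         for s in PARTIAL_VIEW_INSERTS}
    return table


def partial_view_study(seed: int, total_partial: float = 2e6,
                       full: NanoparticleStudy | None = None,
                       total_full: float = 1e7) -> dict:
    """Partial-view vs full-view consistency on the three bottom inserts.

    Returns per-method tables of insert intensities normalised by their
    three-insert average, with the located-event counts that set the
    Poisson standard errors.  The partial view uses two opposing beams and
    roughly the full/partial primary ratio of the full-scale study.
    """
    rng = np.random.default_rng(seed)
    if full is None:
        full = nanoparticle_study(int(rng.integers(2 ** 31)),
                                  total_primaries=total_full)
    phantom = full.phantom
    plan_spbe = partial_view_plan("SPBE").scaled_to(total_partial / 2)
    plan_ve = partial_view_plan("VE").scaled_to(total_partial / 2)
    acq_spbe = run_acquisition(phantom, plan_spbe, SPB_RING, rng.spawn(1)[0])
    acq_ve = run_acquisition(phantom, plan_ve, TOF_RING, rng.spawn(1)[0])
    flu_partial = pair_weighted_fluence_map(plan_ve, phantom)

    full_table = _insert_table(full.acq_spbe, full.acq_ve, full.plan_spbe,
                               phantom, full.fluence)
    partial_table = _insert_table(acq_spbe, acq_ve, plan_spbe,
                                  phantom, flu_partial)
    return {"full": full_table, "partial": partial_table,
            "full_study": full,
            "acq_partial_spbe": acq_spbe, "acq_partial_ve": acq_ve}


# ---------------------------------------------------------------------------
# Dose monitoring
# ---------------------------------------------------------------------------

def dose_monitoring_study(seed: int, total_primaries: float = 1e6,
                          n_beams: int = 7) -> dict:
    """Radiotherapy-mode monitoring on a synthetic head-like phantom.

    An elliptical water phantom with a bone-like shell insert stands in for
    the patient; ``n_beams`` equally spaced beams converge on a 2 cm target
    off-centre.  Produces the TERMA map, its Gaussian-blurred dose
    surrogate, the P2T ground-truth tally (no fluence correction, matching
    therapy-mode processing) and cIVH curves of the target and of the
    surrounding body, all normalised by the target mean.
    """
    from .analysis import civh, normalize_image
    from .materials import build_elliptical_phantom, get_material
    from .transport import compute_terma

    rng = np.random.default_rng(seed)
    target_center, target_radius = (2.0, 1.5), 1.0
    phantom = build_elliptical_phantom(
        minor=14.0, major=16.0,
        inserts=[((-3.5, -2.0), 1.2, get_material("trabecular_bone"))])

    beams = []
    for k in range(n_beams):
        ang = 360.0 * k / n_beams
        probe = Beam(angle_deg=ang, pencil_offsets=np.array([0.0]),
                     pencil_width=0.5)
        # aim the aperture at the target: lateral offset of the target in
        # the isocentre plane of this beam
        v = np.array(target_center) - probe.source
        off_t = probe.sad * float(v @ probe.lateral) / float(v @ probe.direction)
        n_p = int(np.round(2 * (target_radius + 0.5) / 0.5))
        offsets = off_t + (np.arange(n_p) - (n_p - 1) / 2) * 0.5
        beams.append(Beam(angle_deg=ang, mode="VE", pencil_offsets=offsets,
                          pencil_width=0.5, fluence=np.ones(n_p)))
    plan = BeamPlan(tuple(beams)).scaled_to(total_primaries)

    acq = run_acquisition(phantom, plan,
                          RingDetector(time_resolution_ns=0.3),
                          rng.spawn(1)[0])
    gt = acq.gt_image()
    terma = compute_terma(plan, phantom)
    dose = compute_terma(plan, phantom, blur_sigma_cm=0.5)
    images = {name: normalize_image(img, target_center, target_radius,
                                    mode="target-mean")
              for name, img in (("P2T", gt), ("TERMA", terma),
                                ("dose_surrogate", dose))}

    target_mask = gt.roi_mask(target_center, target_radius)
    body_mask = phantom.material_index > 0
    thresholds = np.linspace(0.0, 1.2, 64)
    curves = {name: {"target": civh(img, target_mask, thresholds),
                     "body": civh(img, body_mask, thresholds)}
              for name, img in images.items()}
    return {"phantom": phantom, "plan": plan, "acq": acq,
            "images": images, "civh": curves, "thresholds": thresholds}
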