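"""End-to-end acquisition: beam plan -> primaries -> pairs -> LORs.

Chains the transport and detection stages in vectorised chunks:

1. schedule primaries per (beam, pencil) with uniform release gaps,
2. trace each primary to its first interaction (Siddon-segment sampling),
3. record ring elements struck by unscattered primaries (per-beam discard
   sets), keep pair-production events,
4. drift positrons (calibrated 3D range law), annihilate, emit back-to-back
   in-plane 511 keV photons,
5. project photons to the ring, apply survival (Bernoulli thinning or
   multiplicative weighting), draw detector response times,
6. optional flat accidental background, energy window, primary-module
   discard, coincidence pairing.

The ground-truth tally (every annihilation, detected or not) is kept
alongside the list-mode LORs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import detection as det
from . import transport as tr
from .beams import BeamPlan, schedule_beams
from .detection import DetectionRecords, LORData, RingDetector
from .materials import PAIR_THRESHOLD_MEV, VoxelPhantom
from .transport import SPEED_OF_LIGHT_CM_NS as C

__all__ = ["Acquisition", "run_acquisition"]


@dataclass
class Acquisition:
    """Result of one simulated acquisition."""

    phantom: VoxelPhantom
    plan: BeamPlan
    ring: RingDetector
    lors: LORData
    truth_points: np.ndarray
    truth_weights: np.ndarray
    n_primaries: int
    n_pair_events: int
    n_records: int
    contaminated: dict[int, np.ndarray]
    config: dict = field(default_factory=dict)
    records: DetectionRecords | None = None

    def gt_image(self) -> Image:
        return tr.tally_ground_truth(self.truth_points, self.truth_weights,
                                     self.phantom)

    @property
    def accepted_pairs(self) -> int:
        return len(self.lors)


def _clip_to_grid(start: np.ndarray, end: np.ndarray, phantom: VoxelPhantom):
    """Clamp displacement endpoints to the grid box along the segment.

    Positrons whose sampled displacement would exit the grid annihilate at
    the exit point (just inside the boundary).  Returns (points, n_clipped).
    """
    xmin, xmax, ymin, ymax = phantom.extent
    eps = 1e-6
    out = end.copy()
    outside = ((end[:, 0] < xmin) | (end[:, 0] >= xmax)
               | (end[:, 1] < ymin) | (end[:, 1] >= ymax))
    if np.any(outside):
        s = start[outside]
        e = end[outside]
        d = e - s
        t = np.ones(len(s))
        for axis, (lo, hi) in enumerate([(xmin, xmax - eps), (ymin, ymax - eps)]):
            with np.errstate(divide="ignore", invalid="ignore"):
                t_lo = (lo - s[:, axis]) / d[:, axis]
                t_hi = (hi - s[:, axis]) / d[:, axis]
            t_axis = np.where(d[:, axis] > 0, t_hi,
                              np.where(d[:, axis] < 0, t_lo, np.inf))
            t = np.minimum(t, np.clip(t_axis, 0.0, 1.0))
        out[outside] = s + t[:, None] * d
    return out, int(np.sum(outside))


def run_acquisition(phantom: VoxelPhantom, plan: BeamPlan, ring: RingDetector,
                    rng: np.random.Generator | int,
                    survival_mode: str = "weight",
                    force_pair: bool = True,
                    importance_energy: bool = True,
                    background_per_record: float = 0.0,
                    range_model: tr.PositronRangeModel | None = None,
                    keep_records: bool = False,
                    chunk_size: int = 2_000_000) -> Acquisition:
    """Simulate a full acquisition and pair the detections into LORs.

    ``survival_mode`` selects Bernoulli thinning ("thin") or multiplicative
    weighting ("weight") for annihilation-photon attenuation;
    ``force_pair`` enables the forced-pair variance reduction and
    ``importance_energy`` draws primary energies from the pair-weighted
    spectrum (with exact p/q weight compensation), so nearly every traced
    primary contributes a usefully weighted pair event.
    ``background_per_record`` adds that many flat accidental records per
    annihilation record (uniform in time, element and 0.05-0.9 MeV energy).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if survival_mode not in ("weight", "thin"):
        raise ValueError("survival_mode must be 'weight' or 'thin'")
    plan.validate_against(phantom)
    spec = phantom.spectrum
    if range_model is None:
        range_model = tr.PositronRangeModel(spectrum=spec, model=phantom.model)
    density_by_mat = np.array([m.density for m in phantom.materials])

    # importance distribution over spectrum bins: q(E) ~ p(E) * (mu_pp/mu_t)
    # in the reference medium, with per-photon weight p/q
    p_bins = spec.probabilities
    if importance_energy:
        from .materials import get_material
        ref = get_material("water")
        ratio = np.asarray(phantom.model.mu_pair(ref, spec.energies)
                           / phantom.model.mu_total(ref, spec.energies))
        q_bins = p_bins * ratio
        if q_bins.sum() <= 0:
            raise ValueError("spectrum has no pair-producing component")
        q_bins = q_bins / q_bins.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            w_energy_by_bin = np.where(q_bins > 0, p_bins / q_bins, 0.0)
        q_cdf = np.cumsum(q_bins)
    else:
        w_energy_by_bin = np.ones_like(p_bins)
        q_cdf = None

    beam_arr, pencil_arr, t_arr, _ = schedule_beams(plan, rng.spawn(1)[0])
    t_arr_ns = t_arr * 1e9
    n_total = beam_arr.size

    sources = np.array([b.source for b in plan.beams])
    laterals = np.array([b.lateral for b in plan.beams])
    offsets = [b.pencil_offsets for b in plan.beams]
    widths = np.array([b.pencil_width for b in plan.beams])

    contaminated: dict[int, set] = {bi: set() for bi in range(plan.n_beams)}
    rec_parts: list[DetectionRecords] = []
    truth_pts: list[np.ndarray] = []
    truth_w: list[np.ndarray] = []
    n_pairs = 0
    event_base = 0

    for lo in range(0, n_total, chunk_size):
        sl = slice(lo, min(lo + chunk_size, n_total))
        b = beam_arr[sl].astype(np.int64)
        p = pencil_arr[sl].astype(np.int64)
        t_inc = t_arr_ns[sl]
        nc = b.size

        origins = sources[b]
        # pencil aim point in the isocentre plane, jittered across the width
        off_val = np.empty(nc)
        for bi in np.unique(b):
            m = b == bi
            off_val[m] = offsets[bi][p[m]]
        off_val = off_val + rng.uniform(-0.5, 0.5, nc) * widths[b]
        targets = off_val[:, None] * laterals[b]
        dirs = targets - origins
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

        if q_cdf is not None:
            ebins = np.searchsorted(q_cdf, rng.random(nc),
                                    side="right").clip(0, spec.n_bins - 1)
        else:
            ebins = spec.sample_bins(nc, rng)
        status, pos, mat, plen, w_evt = tr.trace_primaries(
            origins, dirs, ebins, phantom, rng, force_pair=force_pair)

        # unscattered primaries escape along their original ray
        esc = status == 0
        if np.any(esc):
            elems, _ = det.project_to_ring(origins[esc], dirs[esc], ring)
            for bi in np.unique(b[esc]):
                contaminated[int(bi)].update(
                    np.unique(elems[(b[esc] == bi)]).tolist())

        keep = (status == 3) & (w_evt > 0)
        ne = int(np.sum(keep))
        if ne == 0:
            continue
        n_pairs += ne
        E = spec.energies[ebins[keep]]
        t_plus = rng.random(ne) * np.clip(E - PAIR_THRESHOLD_MEV, 0, None)
        rho = density_by_mat[mat[keep]]
        disp = tr.positron_displacement(t_plus, rho, rng, range_model)
        mag = np.linalg.norm(disp, axis=1)
        ann_raw = pos[keep] + disp[:, :2]
        ann, _ = _clip_to_grid(pos[keep], ann_raw, phantom)
        t_ann = t_inc[keep] + plen[keep] / C + mag / C
        # in-plane pencils spread as 1/r; one extra 1/r power restores the
        # 3D inverse-square fluence the correction model assumes
        sad_b = np.array([bm.sad for bm in plan.beams])[b[keep]]
        r_int = np.linalg.norm(pos[keep] - origins[keep], axis=1)
        w_event = w_evt[keep] * sad_b / r_int * w_energy_by_bin[ebins[keep]]
        truth_pts.append(ann.astype(np.float32))
        truth_w.append(w_event.astype(np.float32))

        u1, u2, e_gamma = tr.emit_annihilation_pair(ne, rng)
        ev_id = event_base + np.arange(ne, dtype=np.int64)
        event_base += ne
        for u in (u1, u2):
            elems, s_ring = det.project_to_ring(ann, u, ring)
            surv = tr.survival_weight(ann, u, phantom)
            if survival_mode == "thin":
                kp = rng.random(ne) < surv
                w_rec = np.ones(int(kp.sum()))
            else:
                kp = np.ones(ne, dtype=bool)
                w_rec = surv
            t_det = det.detection_time(t_ann[kp], s_ring[kp] / C,
                                       ring.time_resolution_ns, rng)
            # compact dtypes: tens of millions of records must fit in RAM;
            # only the detection time needs double precision (ps over ms)
            rec_parts.append(DetectionRecords(
                element=elems[kp].astype(np.int32),
                energy=np.full(int(kp.sum()), e_gamma, dtype=np.float32),
                t=t_det, beam=b[keep][kp].astype(np.int32),
                pencil=p[keep][kp].astype(np.int32),
                event_id=ev_id[kp], weight=w_rec.astype(np.float32),
                event_weight=w_event[kp].astype(np.float32),
                origin=np.full(int(kp.sum()), det.ORIGIN_ANNIHILATION,
                               dtype=np.int8)))

    records = (DetectionRecords.concatenate(rec_parts) if rec_parts
               else DetectionRecords.empty())

    if background_per_record > 0 and len(records) > 0:
        n_bg = int(round(background_per_record * len(records)))
        t_lo, t_hi = records.t.min(), records.t.max()
        rec_bg = DetectionRecords(
            element=rng.integers(0, ring.n_elements, n_bg, dtype=np.int32),
            energy=rng.uniform(0.05, 0.9, n_bg).astype(np.float32),
            t=rng.uniform(t_lo, t_hi, n_bg),
            beam=np.full(n_bg, -1, dtype=np.int32),
            pencil=np.full(n_bg, -1, dtype=np.int32),
            event_id=np.full(n_bg, -1, dtype=np.int64),
            weight=np.ones(n_bg, dtype=np.float32),
            event_weight=np.ones(n_bg, dtype=np.float32),
            origin=np.full(n_bg, det.ORIGIN_BACKGROUND, dtype=np.int8))
        records = DetectionRecords.concatenate([records, rec_bg])

    contaminated_arr = {bi: np.array(sorted(s), dtype=np.int64)
                        for bi, s in contaminated.items()}
    eligible = det.energy_window_filter(records, ring.energy_window)
    cleaned = det.discard_primary_hit_modules(eligible, contaminated_arr)
    lors = det.find_coincidences(cleaned, ring)

    return Acquisition(
        phantom=phantom, plan=plan, ring=ring, lors=lors,
        truth_points=(np.concatenate(truth_pts) if truth_pts
                      else np.empty((0, 2))),
        truth_weights=(np.concatenate(truth_w) if truth_w else np.empty(0)),
        n_primaries=int(n_total), n_pair_events=int(n_pairs),
        n_records=len(records), contaminated=contaminated_arr,
        config={"survival_mode": survival_mode, "force_pair": force_pair,
                "background_per_record": background_per_record},
        records=records if keep_records else None)
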