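"""Synthetic study generator.

Emulates the study design end to end: 22 patients (SZQ) and 23 controls
(CTRL) each watch four 5-minute videos (two audio-visually synchronized, two
non-synchronized), answer probes every 60 +/- 10 s with one of four
cognitive states (Audio, Image, Full, MW), and contribute 50-s pre-probe
EEG segments at 500 Hz over the 31-electrode 10-20 montage.

Signal complexity is state-dependent by construction: every
(group, synchrony, answer, area) cell has a Hurst exponent H, and channels
in that cell carry fractional Brownian motion whose theoretical fractal
dimension is 2 - H. The default cell table encodes the study's qualitative
pattern — frontal areas rougher than occipito-parietal ones, and an MW > Full
complexity elevation confined to controls in the synchronized condition and
absent in occipito-parietal areas. Default answer probabilities likewise
follow the reported pattern (controls Full-dominant, patients with elevated
mind wandering, both modulated by synchrony). These defaults are
illustrative study conditions, not estimates of the real data.

Randomness is hierarchical: one root seed is split per participant and
stream, so adding a participant leaves everyone else's data untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from .design import schedule_probes
from .fbm import simulate_fbm
from .montage import MONTAGE_31, REGIONS, RegionMap, default_region_map
from .preprocess import ANSWERS, EEGSegment, ProbeResponse

__all__ = [
    "SynthConfig",
    "Participant",
    "simulate_fbm",
    "default_hurst_by_cell",
    "default_answer_probs",
    "null_config",
    "make_participants",
    "simulate_responses",
    "simulate_participant_eeg",
    "simulate_cognitive_profiles",
    "simulate_hfd_records",
    "simulate_study",
]

GROUPS = ("CTRL", "SZQ")
SYNCS = ("Sync", "NoSync")

#: baseline Hurst exponent per area: frontal rougher (higher FD), occipital smoother
_BASE_HURST = {
    "F": 0.45, "FL": 0.45, "FR": 0.45,
    "CL": 0.50, "CR": 0.50, "TL": 0.50, "TR": 0.50,
    "OP": 0.55, "OPL": 0.55, "OPR": 0.55,
}
_OCCIPITAL = ("OP", "OPL", "OPR")


def default_hurst_by_cell(mw_gap: float = 0.03) -> dict[tuple[str, str, str, str], float]:
    """Hurst table with an MW-Full gap only for CTRL in Sync, non-occipital areas.

    ``mw_gap`` lowers H (raises FD by the same amount) for MW segments in the
    affected cells; 0.03 is a realistic between-state fractal-dimension
    difference for band-limited scalp EEG.
    """
    table: dict[tuple[str, str, str, str], float] = {}
    for g in GROUPS:
        for s in SYNCS:
            for a in ANSWERS:
                for area in REGIONS:
                    h = _BASE_HURST[area]
                    if (g, s, a) == ("CTRL", "Sync", "MW") and area not in _OCCIPITAL:
                        h -= mw_gap
                    table[(g, s, a, area)] = h
    return table


def default_answer_probs() -> dict[tuple[str, str], tuple[float, float, float, float]]:
    """(Audio, Image, Full, MW) probabilities per (group, synchrony).

    Qualitative pattern of the reported box plots: controls are
    Full-attention-dominant, patients show elevated MW, and desynchronized
    audio/image raises MW in both groups (more so in controls, producing the
    three-way interaction).
    """
    return {
        ("CTRL", "Sync"): (0.06, 0.10, 0.64, 0.20),
        ("CTRL", "NoSync"): (0.10, 0.14, 0.44, 0.32),
        ("SZQ", "Sync"): (0.06, 0.10, 0.42, 0.42),
        ("SZQ", "NoSync"): (0.07, 0.11, 0.34, 0.48),
    }


# standardized group deficits (Cohen's d, CTRL minus SZQ) for cognitive scores
_SCIP_SHIFTS = {"VLi": 0.71, "VLd": 0.36, "VF": 0.96, "WM": 0.46, "PV": 1.02}
_D2_TR_SHIFT = 1.09


@dataclass
class SynthConfig:
    """Generator configuration; defaults are the study conditions."""

    n_ctrl: int = 23
    n_szq: int = 22
    sfreq: float = 500.0
    n_channels: int = 31
    segment_length: float = 50.0
    segments_per_participant: int = 20
    hurst_by_cell: dict = field(default_factory=default_hurst_by_cell)
    answer_probs: dict = field(default_factory=default_answer_probs)
    # observation noise relative to unit signal SD; HFD probes 2-20 ms lags,
    # where broadband noise dominates quickly, so the default is small
    noise_sd: float = 0.002
    seed: int = 0
    # record-level HFD generator (between-participant and residual SD)
    hfd_participant_sd: float = 0.05
    hfd_noise_sd: float = 0.05
    # cognitive-score group shifts (standardized); zero => null generator
    scip_shifts: dict = field(default_factory=lambda: dict(_SCIP_SHIFTS))
    d2_tr_shift: float = _D2_TR_SHIFT
    video_length_s: float = 300.0
    probe_gap_s: float = 60.0
    probe_jitter_s: float = 10.0

    def __post_init__(self) -> None:
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.n_channels != len(MONTAGE_31):
            raise ValueError("n_channels must match the 31-electrode montage")
        for cell, h in self.hurst_by_cell.items():
            if not 0.0 < h < 1.0:
                raise ValueError(f"Hurst for {cell} must lie in (0,1), got {h}")
        for key, probs in self.answer_probs.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"answer probabilities for {key} must sum to 1")

    # --- config (de)serialization: YAML mirrors the dataclass exactly ------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["hurst_by_cell"] = {"|".join(k): v for k, v in self.hurst_by_cell.items()}
        d["answer_probs"] = {"|".join(k): list(v) for k, v in self.answer_probs.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["hurst_by_cell"] = {tuple(k.split("|")): v for k, v in d["hurst_by_cell"].items()}
        d["answer_probs"] = {tuple(k.split("|")): tuple(v) for k, v in d["answer_probs"].items()}
        return cls(**d)


def null_config(**overrides) -> SynthConfig:
    """A generator with identical group parameters and no injected effects.

    Every design cell (including areas) shares one Hurst exponent and every
    (group, synchrony) shares one answer distribution, so all fixed effects
    are exactly null.
    """
    probs = (0.10, 0.10, 0.50, 0.30)
    flat = {cell: 0.5 for cell in default_hurst_by_cell()}
    cfg = SynthConfig(
        hurst_by_cell=flat,
        answer_probs={(g, s): probs for g in GROUPS for s in SYNCS},
        scip_shifts={k: 0.0 for k in _SCIP_SHIFTS},
        d2_tr_shift=0.0,
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass(frozen=True)
class Participant:
    """One study participant; clinical fields are present only for SZQ."""

    id: str
    group: str
    age: float
    gender: str
    handedness: str
    illness_duration: float | None = None
    chlorpromazine_equiv: float | None = None
    antidepressant: bool | None = None
    mood_stabilizer: bool | None = None

    def __post_init__(self) -> None:
        clinical = (self.illness_duration, self.chlorpromazine_equiv,
                    self.antidepressant, self.mood_stabilizer)
        if self.group == "CTRL" and any(v is not None for v in clinical):
            raise ValueError("clinical fields must be absent for CTRL")
        if self.group == "SZQ" and any(v is None for v in clinical):
            raise ValueError("clinical fields required for SZQ")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def make_participants(cfg: SynthConfig) -> list[Participant]:
    """Demographics drawn near the reported sample characteristics."""
    out: list[Participant] = []
    for idx in range(cfg.n_ctrl + cfg.n_szq):
        group = "CTRL" if idx < cfg.n_ctrl else "SZQ"
        rng = _rng(cfg.seed, 0, idx)
        age = float(np.clip(rng.normal(38.9 if group == "CTRL" else 36.5, 11.0), 23, 57))
        gender = "F" if rng.random() < (0.18 if group == "CTRL" else 0.30) else "M"
        handed = "L" if (group == "CTRL" and rng.random() < 0.09) else "R"
        if group == "SZQ":
            out.append(Participant(
                id=f"P{idx + 1:02d}", group=group, age=age, gender=gender,
                handedness=handed,
                illness_duration=float(np.clip(rng.normal(14.68, 9.53), 1, 35)),
                chlorpromazine_equiv=float(np.clip(rng.normal(676.14, 359.43), 50, None)),
                antidepressant=bool(rng.random() < 3 / 22),
                mood_stabilizer=bool(rng.random() < 11 / 22),
            ))
        else:
            out.append(Participant(id=f"P{idx + 1:02d}", group=group, age=age,
                                   gender=gender, handedness=handed))
    return out


def simulate_responses(
    participant: Participant,
    cfg: SynthConfig,
    seed: int | None = None,
    video_syncs: tuple[str, ...] = ("Sync", "NoSync", "Sync", "NoSync"),
) -> list[ProbeResponse]:
    """Probe schedule and multinomial answers for one participant.

    Four 300-s videos; gaps between probes U(gap - jitter, gap + jitter);
    answers drawn from the participant's (group, synchrony) probability cell.
    """
    root = cfg.seed if seed is None else seed
    p_idx = int(participant.id.lstrip("P"))
    out: list[ProbeResponse] = []
    for v_idx, sync in enumerate(video_syncs):
        rng = _rng(root, 1, p_idx, v_idx)
        times = schedule_probes(cfg.video_length_s, cfg.probe_gap_s,
                                cfg.probe_jitter_s, seed=rng)
        probs = cfg.answer_probs[(participant.group, sync)]
        answers = rng.choice(ANSWERS, size=len(times), p=np.asarray(probs))
        for t, a in zip(times, answers):
            out.append(ProbeResponse(
                participant_id=participant.id, video_idx=v_idx,
                probe_time_s=float(t), synchrony=sync, answer=str(a),
            ))
    return out


def simulate_participant_eeg(
    participant: Participant,
    cfg: SynthConfig,
    responses: list[ProbeResponse],
    region_map: RegionMap | None = None,
) -> list[EEGSegment]:
    """One labeled EEG segment per probe response.

    Each channel carries an independent unit-variance fBm path whose Hurst
    exponent is the (group, synchrony, answer, area) cell value for the
    channel's area, plus additive white observation noise of SD
    ``cfg.noise_sd``.
    """
    rmap = region_map if region_map is not None else default_region_map()
    n_samp = int(round(cfg.segment_length * cfg.sfreq))
    p_idx = int(participant.id.lstrip("P"))
    segments: list[EEGSegment] = []
    for s_idx, resp in enumerate(responses):
        data = np.empty((len(MONTAGE_31), n_samp))
        for c_idx, ch in enumerate(MONTAGE_31):
            area = rmap.mapping[ch]
            h = cfg.hurst_by_cell[(participant.group, resp.synchrony, resp.answer, area)]
            rng = _rng(cfg.seed, 2, p_idx, s_idx, c_idx)
            path = simulate_fbm(n_samp, h, rng)
            path = (path - path.mean()) / max(path.std(), 1e-12)
            data[c_idx] = path + cfg.noise_sd * rng.standard_normal(n_samp)
        segments.append(EEGSegment(
            participant_id=participant.id, channels=MONTAGE_31, sfreq=cfg.sfreq,
            data=data, answer=resp.answer, synchrony=resp.synchrony,
            t0=resp.probe_time_s - cfg.segment_length,
        ))
    return segments


def simulate_cognitive_profiles(
    participants: list[Participant], cfg: SynthConfig, seed: int | None = None
) -> pd.DataFrame:
    """Cognitive and clinical score table, one row per participant.

    SCIP subtests are standardized Gaussians with configurable group deficits;
    D2 raw counts use a Gaussian total-responses scale with negative-binomial
    omission/commission errors (right-skewed, so normality screening routes
    them to the median test); PANSS subscales (SZQ only) are drawn at the
    reported subscale means and SDs.
    """
    if not participants:
        raise ValueError("participants must be non-empty")
    root = cfg.seed if seed is None else seed
    rows = []
    for p in participants:
        rng = _rng(root, 3, int(p.id.lstrip("P")))
        shift = 1.0 if p.group == "SZQ" else 0.0
        row: dict = {"participant_id": p.id, "group": p.group, "age": p.age,
                     "gender": p.gender}
        for name, d in cfg.scip_shifts.items():
            row[f"SCIP_{name}"] = rng.normal(-d * shift, 1.0)
        tr = int(np.clip(rng.normal(450 - shift * cfg.d2_tr_shift * 80, 80), 150, 700))
        o = int(rng.negative_binomial(3, 3 / (3 + 20.0)))  # mean 20, skewed
        c = int(rng.negative_binomial(2, 2 / (2 + 8.0)))  # mean 8, skewed
        th = max(tr - o - c, 0)
        per_line = tr / 14.0
        tr_plus = int(round(per_line * rng.uniform(1.1, 1.3)))
        tr_minus = int(round(per_line * rng.uniform(0.7, 0.9)))
        row.update(D2_TR=tr, D2_TH=th, D2_O=o, D2_C=c,
                   D2_TRplus=tr_plus, D2_TRminus=max(tr_minus, 0))
        if p.group == "SZQ":
            row.update(
                PANSS_positive=rng.normal(14.0, 6.08),
                PANSS_negative=rng.normal(18.85, 7.60),
                PANSS_general=rng.normal(32.41, 9.33),
                illness_duration=p.illness_duration,
                chlorpromazine_equiv=p.chlorpromazine_equiv,
                antidepressant=p.antidepressant,
                mood_stabilizer=p.mood_stabilizer,
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    if "PANSS_positive" in df:
        df["PANSS_total"] = (df["PANSS_positive"] + df["PANSS_negative"]
                             + df["PANSS_general"])
    return df


def simulate_hfd_records(
    participants: list[Participant],
    cfg: SynthConfig,
    seed: int | None = None,
    responses: dict[str, list[ProbeResponse]] | None = None,
) -> pd.DataFrame:
    """Record-level HFD table for mixed-model simulations.

    For each probe response and each of the 10 areas, draws
    hfd = (2 - H(cell)) + b_participant + noise, with b ~ N(0,
    hfd_participant_sd) and noise ~ N(0, hfd_noise_sd). This is the
    distributional shortcut for the signal path (fBm synthesis -> Higuchi
    estimation -> area averaging), whose mean structure it shares by the
    FD = 2 - H identity; the signal path itself is validated separately.
    """
    root = cfg.seed if seed is None else seed
    rows = []
    for p in participants:
        p_idx = int(p.id.lstrip("P"))
        rng = _rng(root, 4, p_idx)
        b_i = rng.normal(0.0, cfg.hfd_participant_sd)
        resp = (responses or {}).get(p.id)
        if resp is None:
            resp = simulate_responses(p, cfg, seed=root)
        for r in resp:
            for area in REGIONS:
                h = cfg.hurst_by_cell[(p.group, r.synchrony, r.answer, area)]
                rows.append({
                    "participant_id": p.id, "group": p.group,
                    "synchrony": r.synchrony, "answer": r.answer, "area": area,
                    "hfd": (2.0 - h) + b_i + rng.normal(0.0, cfg.hfd_noise_sd),
                })
    return pd.DataFrame(rows)


def responses_to_frame(responses: list[ProbeResponse], group_of: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant_id": r.participant_id,
        "group": group_of[r.participant_id],
        "video_idx": r.video_idx,
        "probe_time_s": r.probe_time_s,
        "synchrony": r.synchrony,
        "answer": r.answer,
    } for r in responses])


def simulate_study(cfg: SynthConfig, with_eeg: bool = False):
    """Generate a full study: participants, responses, profiles (and EEG).

    Returns (participants, responses_frame, profiles_frame, segments) where
    segments is a dict participant_id -> list[EEGSegment] (empty when
    with_eeg is False — the record-level generator covers statistics-only
    runs).
    """
    participants = make_participants(cfg)
    all_resp: list[ProbeResponse] = []
    segments: dict[str, list[EEGSegment]] = {}
    for p in participants:
        resp = simulate_responses(p, cfg)
        all_resp.extend(resp)
        if with_eeg:
            segments[p.id] = simulate_participant_eeg(p, cfg, resp)
    group_of = {p.id: p.group for p in participants}
    responses = responses_to_frame(all_resp, group_of)
    profiles = simulate_cognitive_profiles(participants, cfg)
    return participants, responses, profiles, segments
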