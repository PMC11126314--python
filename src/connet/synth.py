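"""Seed-reproducible synthetic iEEG cohorts with known ground truth.

Each patient carries a mirrored bilateral SEEG-style montage (up to three
depth electrodes per hemisphere, up to 12 contacts each, e.g. LA01..LA12 and
RA01..RA12).  Per channel the signal is a sum of

1. pink (1/f) background noise,
2. band-limited oscillations; both components are coloured by a within-
   electrode spatial correlation profile (exp(-corr_decay * d) by default,
   or a smoother Gaussian profile exp(-corr_decay * d^2)), so the
   adjacent-contact correlation matches the profile by construction,
3. a common reference source added identically to every channel (machine-
   reference contamination; exactly cancelled by either montage),
4. spike-like biphasic transients at a configurable rate (optionally
   elevated on the SOZ side),
5. planted hemispheric asymmetries: a coupling gain on the SOZ side's
   spatial correlation (targets coherence/PLV/correlation measures) and an
   alternating static log-amplitude offset on SOZ-side channels (targets
   relative entropy, which compares amplitude distributions, while leaving
   scale-invariant measures untouched).

Multiplicative gains are applied to the neural part only, before the
reference source is added, so common-mode cancellation stays exact.
The generator writes the plain array container (``.npy`` + channel CSV +
ground-truth JSON) plus a cohort manifest; all draws flow from one seed.
"""

from __future__ import annotations

import json
import logging
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import ChannelInfo, EpochSet, Recording, bandpass_array, format_channel_label

logger = logging.getLogger("connet")


@dataclass
class CohortConfig:
    n_patients: int = 20
    electrodes_per_hemisphere: int = 3
    contacts_per_electrode: int = 12
    fs: float = 512.0
    n_epochs: int = 5
    epoch_s: float = 120.0
    base_amp_uv: float = 50.0
    ref_contamination_var: float = 1.0 / 3.0  # relative to unit neural variance
    corr_decay: float = 1.0
    corr_shape: str = "exp"                   # "exp" (AR(1)-like) or "gaussian" (smooth spread)
    osc_band: tuple[float, float] = (4.0, 30.0)
    osc_frac: float = 0.35
    global_frac: float = 0.25                 # widely shared source, smooth gain profile
    global_band: tuple[float, float] | None = None  # None -> broadband pink source
    grad_frac: float = 0.0                    # per-electrode rhythm with linear gain gradient
    grad_band: tuple[float, float] | None = None  # None -> broadband pink rhythm
    network_frac: float = 0.0                 # patch-pair sources, smooth positive gains
    network_patch: int = 4                    # contacts per patch
    soz_sides: list[str] | None = None        # default: alternate L/R
    coupling_effect: float = 1.0              # SOZ-side correlation gain (<1 lowers FC)
    re_effect: float = 1.0                    # SOZ-side log-gain offset, in units of channel_gain_sigma, +1
    window_jitter_sigma: float = 0.0          # baseline lognormal sigma, per 2-s block
    channel_gain_sigma: float = 0.0           # static per-channel lognormal sigma
    electrode_gain_sigma: float = 0.0         # static per-electrode lognormal sigma
    spike_rate: float = 0.0                   # events per channel-minute
    spike_soz_multiplier: float = 1.0
    spike_amp: float = 5.0                    # in units of channel SD
    artifact_channel_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.electrodes_per_hemisphere > 3 or self.contacts_per_electrode > 12:
            raise ValueError("montage exceeds 3 electrodes x 12 contacts per "
                             "hemisphere")
        if self.coupling_effect < 0:
            raise ValueError("coupling_effect must be >= 0")

    @property
    def n_channels(self) -> int:
        return 2 * self.electrodes_per_hemisphere * self.contacts_per_electrode

    def soz_side(self, patient_index: int) -> str:
        if self.soz_sides is not None:
            return self.soz_sides[patient_index]
        return "L" if patient_index % 2 == 0 else "R"


def similarity_benchmark_config(seed: int | None = None, **overrides) -> CohortConfig:
    """Cohort construction for the pipeline-similarity benchmark.

    The signal model is chosen so the three known pipeline families are
    distinguishable: amplitude-scale heterogeneity (electrode- and channel-
    level gains plus window jitter) gives relative-entropy networks their own
    structure, invisible to scale-invariant measures; a widely shared source
    with smooth gains is retained by the common average but cancelled by the
    bipolar montage; smooth (Gaussian) spatial spread plus per-electrode
    gradient rhythms keep bipolar derivative correlations predominantly
    positive so signed and unsigned measures agree within a montage.
    """
    base = dict(n_patients=3, electrodes_per_hemisphere=3,
                contacts_per_electrode=4, fs=256.0, n_epochs=5, epoch_s=40.0,
                corr_shape="gaussian", corr_decay=0.1,
                osc_frac=0.0, global_frac=0.0, grad_frac=0.25,
                network_frac=0.45, network_patch=2,
                electrode_gain_sigma=1.0, channel_gain_sigma=0.1,
                window_jitter_sigma=0.1, seed=seed)
    base.update(overrides)
    return CohortConfig(**base)


def lateralization_benchmark_config(seed: int | None = None,
                                    re_effect: float = 2.6,
                                    **overrides) -> CohortConfig:
    """Cohort construction for the SOZ-lateralization benchmark.

    Twenty patients with mirrored bilateral montages; seizure-onset-side
    channels get an alternating static log-amplitude offset of
    ``channel_gain_sigma * (re_effect - 1)``.  Static gains are invisible to
    correlation-, coherence- and phase-based measures, so only
    relative-entropy pipelines carry the planted laterality signal (the
    default offset realizes a paired Cohen's d of roughly 1 on the
    common-average RE pipelines); with ``re_effect=1`` the cohort is a null
    for every pipeline.
    """
    base = dict(n_patients=20, electrodes_per_hemisphere=2,
                contacts_per_electrode=4, fs=256.0, n_epochs=5, epoch_s=20.0,
                corr_shape="gaussian", corr_decay=0.1,
                osc_frac=0.0, global_frac=0.0, grad_frac=0.25,
                network_frac=0.45, network_patch=2,
                electrode_gain_sigma=0.1, channel_gain_sigma=0.15,
                window_jitter_sigma=0.1, re_effect=re_effect, seed=seed)
    base.update(overrides)
    return CohortConfig(**base)


def make_montage(cfg: CohortConfig) -> list[ChannelInfo]:
    """Mirrored bilateral montage: LA01.., LB.., RA01.., ... in order."""
    channels = []
    for side in ("L", "R"):
        for e in range(cfg.electrodes_per_hemisphere):
            elec = side + string.ascii_uppercase[e]
            for c in range(1, cfg.contacts_per_electrode + 1):
                channels.append(ChannelInfo(
                    label=format_channel_label(elec, c), electrode=elec,
                    contact_index=c, hemisphere=side, tissue="grey"))
    return channels


def _pink_noise(rng: np.random.Generator, shape: tuple, fs: float) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    F = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = 1.0 / np.sqrt(f[nz])
    scale[0] = 0.0
    x = np.fft.irfft(F * scale, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _spike_waveform(fs: float) -> np.ndarray:
    """Biphasic 70-ms sharp wave followed by a 300-ms slow wave."""
    n_fast = int(round(0.070 * fs))
    n_slow = int(round(0.300 * fs))
    t_fast = np.linspace(0, 2 * np.pi, n_fast, endpoint=False)
    fast = np.sin(t_fast)
    t_slow = np.linspace(0, np.pi, n_slow, endpoint=False)
    slow = -0.4 * np.sin(t_slow)
    return np.concatenate([fast, slow])


def _side_mixing(cfg: CohortConfig, is_soz: bool) -> np.ndarray:
    """Cholesky factor of the within-electrode target correlation; on the
    SOZ side the off-diagonal is multiplied by coupling_effect."""
    m = cfg.contacts_per_electrode
    idx = np.arange(m)
    d = np.abs(idx[:, None] - idx[None, :])
    if cfg.corr_shape == "gaussian":
        # smooth spatial spread: neighbouring bipolar derivatives stay
        # positively correlated, unlike the exp (AR(1)-like) profile
        C = np.exp(-cfg.corr_decay * d.astype(float) ** 2)
    elif cfg.corr_shape == "exp":
        C = np.exp(-cfg.corr_decay * d.astype(float))
    else:
        raise ValueError(f"unknown corr_shape {cfg.corr_shape!r}")
    if is_soz and cfg.coupling_effect != 1.0:
        off = ~np.eye(m, dtype=bool)
        C[off] *= cfg.coupling_effect
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("target correlation matrix is not positive definite "
                         f"(coupling_effect={cfg.coupling_effect})") from exc


def generate_patient(cfg: CohortConfig, patient_index: int
                     ) -> tuple[Recording, dict]:
    """One patient's continuous machine-referenced recording + ground truth.

    The recording spans ``n_epochs * epoch_s`` seconds starting at 13:00
    (seconds-of-day), so the clock-windowed epoch selector works on it
    unchanged.
    """
    seed = (0 if cfg.seed is None else cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, patient_index]))
    channels = make_montage(cfg)
    n_ch = len(channels)
    n = int(round(cfg.n_epochs * cfg.epoch_s * cfg.fs))
    soz = cfg.soz_side(patient_index)

    data = np.empty((n_ch, n))
    truth: dict = {"patient_index": patient_index, "soz_side": soz,
                   "artifact_channels": [], "spikes": {}}
    pink_frac = (1.0 - cfg.osc_frac - cfg.global_frac - cfg.grad_frac
                 - cfg.network_frac)
    if pink_frac < 0:
        raise ValueError("component variance fractions must sum to <= 1")
    row = 0
    for side in ("L", "R"):
        L = _side_mixing(cfg, is_soz=(side == soz))
        for _e in range(cfg.electrodes_per_hemisphere):
            m = cfg.contacts_per_electrode
            pink = _pink_noise(rng, (m, n), cfg.fs)
            osc = rng.standard_normal((m, n))
            osc = bandpass_array(osc, cfg.fs, cfg.osc_band[0],
                                 min(cfg.osc_band[1], 0.45 * cfg.fs),
                                 warn_clip=False)
            osc /= osc.std(axis=-1, keepdims=True)
            src = (np.sqrt(pink_frac) * pink
                   + np.sqrt(cfg.osc_frac) * osc)
            # both background and oscillation volume-conduct along the shaft
            data[row:row + m] = L @ src
            row += m

    # a widely shared source whose gain varies smoothly along each electrode
    # (volume-conduction-like): survives the common average (gains differ
    # across channels) but nearly cancels in bipolar derivatives
    if cfg.global_frac > 0:
        if cfg.global_band is None:
            s = _pink_noise(rng, (n,), cfg.fs)
        else:
            s = rng.standard_normal(n)
            s = bandpass_array(s, cfg.fs, cfg.global_band[0],
                               min(cfg.global_band[1], 0.45 * cfg.fs),
                               warn_clip=False)
        s /= s.std()
        m = cfg.contacts_per_electrode
        gains = np.empty(n_ch)
        pos = (np.arange(m) / max(m - 1, 1))
        for e in range(2 * cfg.electrodes_per_hemisphere):
            base = rng.uniform(0.4, 1.6)
            slope = rng.uniform(-0.5, 0.5)
            gains[e * m:(e + 1) * m] = base + slope * pos
        data += np.sqrt(cfg.global_frac) * gains[:, None] * s[None, :]
        truth["global_gains"] = gains.tolist()

    # long-range "network" sources: each couples a contact patch on one
    # electrode with a patch on another, with a gain that is constant inside
    # the patch.  The common average sees genuine positive cross-electrode
    # edges between member patches; bipolar derivatives cancel the source
    # except at patch boundaries.  Small patches keep the source's share of
    # the montage mean low, so the negative common-average residue stays a
    # near-uniform bias rather than structure.
    if cfg.network_frac > 0:
        m = cfg.contacts_per_electrode
        n_elec = 2 * cfg.electrodes_per_hemisphere
        patch = min(cfg.network_patch, m)
        G = np.zeros((n_ch, n_elec))   # channel x source gains
        partners = []
        for k in range(n_elec):
            a = k
            b = int(rng.choice([f for f in range(n_elec) if f != a]))
            partners.append((a, b))
            for e in (a, b):
                start = int(rng.integers(0, m - patch + 1))
                G[e * m + start:e * m + start + patch, k] = 1.0
        norms = np.sqrt((G ** 2).sum(axis=1))
        covered = norms > 0
        G[covered] *= (np.sqrt(cfg.network_frac) / norms[covered])[:, None]
        U = np.stack([_pink_noise(rng, (n,), cfg.fs) for _ in range(n_elec)])
        data += G @ U
        if (~covered).any():  # keep per-channel variance budget exact
            data[~covered] += (np.sqrt(cfg.network_frac)
                               * _pink_noise(rng, (int((~covered).sum()), n), cfg.fs))
        truth["network_partners"] = partners

    # per-electrode rhythm projecting with a linear gain gradient along the
    # shaft (dipolar-sheet-like): every bipolar derivative on the electrode
    # inherits the same slope * rhythm term, so derivative signals stay
    # positively correlated within an electrode
    if cfg.grad_frac > 0:
        m = cfg.contacts_per_electrode
        pos = np.arange(m) / max(m - 1, 1) - 0.5
        profile = pos / np.sqrt(np.mean(pos ** 2))   # unit-RMS gain profile
        for e in range(2 * cfg.electrodes_per_hemisphere):
            if cfg.grad_band is None:
                u = _pink_noise(rng, (n,), cfg.fs)
            else:
                u = rng.standard_normal(n)
                u = bandpass_array(u, cfg.fs, cfg.grad_band[0],
                                   min(cfg.grad_band[1], 0.45 * cfg.fs),
                                   warn_clip=False)
            u /= u.std()
            sign = rng.choice([-1.0, 1.0])
            data[e * m:(e + 1) * m] += (np.sqrt(cfg.grad_frac) * sign
                                        * profile[:, None] * u[None, :])

    # spike-like transients (neural, so added before gains and reference)
    wave = _spike_waveform(cfg.fs)
    minutes = n / cfg.fs / 60.0
    for i, ch in enumerate(channels):
        rate = cfg.spike_rate * (cfg.spike_soz_multiplier
                                 if ch.hemisphere == soz else 1.0)
        n_events = rng.poisson(rate * minutes)
        starts = np.sort(rng.integers(0, max(1, n - wave.size), size=n_events))
        for s in starts:
            data[i, s:s + wave.size] += cfg.spike_amp * wave[:n - s]
        if n_events:
            truth["spikes"][ch.label] = (starts / cfg.fs).tolist()

    # amplitude gains: static per channel + per-2-s-block jitter,
    # each normalized to unit mean square so target variance is preserved
    if cfg.channel_gain_sigma > 0 or cfg.electrode_gain_sigma > 0:
        m = cfg.contacts_per_electrode
        ze = np.repeat(rng.standard_normal(2 * cfg.electrodes_per_hemisphere), m)
        zc = rng.standard_normal(n_ch)
        # the SOZ side gets an alternating +-delta log-amplitude offset on
        # top of the baseline spread: only amplitude-distribution measures
        # (relative entropy) can see a static gain, so this plants an
        # RE-specific hemispheric asymmetry, and the bounded offset keeps
        # the realized effect size stable across cohort draws
        delta = cfg.channel_gain_sigma * (cfg.re_effect - 1.0)
        offset = np.array([delta * (1.0 if ch.contact_index % 2 else -1.0)
                           if ch.hemisphere == soz else 0.0
                           for ch in channels])
        g = np.exp(cfg.electrode_gain_sigma * ze
                   + cfg.channel_gain_sigma * zc + offset
                   - cfg.electrode_gain_sigma ** 2
                   - cfg.channel_gain_sigma ** 2)
        data *= g[:, None]
        truth["channel_gains"] = g.tolist()
    if cfg.window_jitter_sigma > 0:
        block = int(round(2.0 * cfg.fs))
        n_blocks = int(np.ceil(n / block))
        gw = np.exp(cfg.window_jitter_sigma
                    * rng.standard_normal((n_ch, n_blocks))
                    - cfg.window_jitter_sigma ** 2)
        data *= np.repeat(gw, block, axis=1)[:, :n]

    # common machine-reference contamination (identical on every channel)
    if cfg.ref_contamination_var > 0:
        ref = rng.standard_normal(n) * np.sqrt(cfg.ref_contamination_var)
        data += ref[None, :]

    # artifact channels: strong line noise plus amplitude bursts
    n_art = int(np.floor(cfg.artifact_channel_fraction * n_ch))
    if n_art:
        art_idx = rng.choice(n_ch, size=n_art, replace=False)
        t = np.arange(n) / cfg.fs
        for i in art_idx:
            data[i] += 6.0 * np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
            burst = rng.random(n) < 0.03
            data[i, burst] += rng.choice([-25.0, 25.0], size=int(burst.sum()))
            truth["artifact_channels"].append(channels[i].label)

    data *= cfg.base_amp_uv
    rec = Recording(data=data, fs=cfg.fs, channels=channels, scheme="machine",
                    epoch_start=13 * 3600.0)
    return rec, truth


def patient_epoch_set(cfg: CohortConfig, patient_index: int
                      ) -> tuple[EpochSet, dict]:
    """Generate a patient and slice the recording into its consecutive
    epochs (aligned with the generator's 2-s gain blocks)."""
    rec, truth = generate_patient(cfg, patient_index)
    n_per = int(round(cfg.epoch_s * cfg.fs))
    epochs = [Recording(data=rec.data[:, i * n_per:(i + 1) * n_per],
                        fs=cfg.fs, channels=rec.channels, scheme="machine",
                        epoch_start=rec.epoch_start + i * cfg.epoch_s)
              for i in range(cfg.n_epochs)]
    return EpochSet(epochs=epochs, epoch_length_s=cfg.epoch_s), truth


@dataclass
class CohortData:
    config: CohortConfig
    patients: list[tuple[str, EpochSet, dict]] = field(default_factory=list)
    manifest: pd.DataFrame | None = None


def generate_cohort(cfg: CohortConfig, outdir: str | Path | None = None) -> CohortData:
    """Generate the full cohort; optionally write array-container files and
    a manifest CSV consumable by the lateralization stage."""
    cohort = CohortData(config=cfg)
    rows = []
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    for i in range(cfg.n_patients):
        pid = f"synth{i:03d}"
        es, truth = patient_epoch_set(cfg, i)
        cohort.patients.append((pid, es, truth))
        row = {"patient": pid, "soz_side": truth["soz_side"],
               "n_channels": len(es.channels), "fs": cfg.fs}
        if outdir is not None:
            from .signals import write_array

            full = np.concatenate([ep.data for ep in es.epochs], axis=1)
            rec = Recording(data=full, fs=cfg.fs, channels=es.channels)
            prefix = outdir / pid
            write_array(rec, prefix)
            with open(f"{prefix}_truth.json", "w") as fh:
                json.dump(truth, fh)
            row["recording"] = f"{pid}.npy"
            row["channels"] = f"{pid}_channels.csv"
        rows.append(row)
    cohort.manifest = pd.DataFrame(rows)
    if outdir is not None:
        cohort.manifest.to_csv(outdir / "manifest.csv", index=False)
    return cohort
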