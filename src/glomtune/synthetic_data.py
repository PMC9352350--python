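"""Synthetic glomerular-response data with the statistical structure of
low-concentration odorant mapping experiments.

The generator emulates a study design in which a large, structurally diverse
odorant panel (default 185 odorants in 16 nominal structural classes) is
delivered at perithreshold concentrations to several mice while sensory input
to every dorsal-OB glomerulus is imaged bilaterally (default 4 mice x 2 OBs).
Its ground truth consists of glomerulus *types* that are conserved across
OBs, each narrowly tuned to a small set of odorants drawn predominantly from
one structural class:

* response amplitudes are lognormal, ln(dF/F%) ~ N(1.48, 1.03);
* a configurable fraction of types (default 0.29) respond to exactly one
  odorant, and co-tuning breadth is otherwise 2 + Poisson with the rate
  calibrated so the median number of responsive glomeruli per odorant hits
  the configured sparsity target (default 2);
* a subset of types is planted as *diagnostic*: their primary odorant is
  exclusive to them, so that odorant singularly activates one glomerulus in
  every OB where the type is present;
* each type has a home position near its class's spatial center (classes are
  spatially clustered by default) plus per-OB Gaussian jitter (default
  s.d. 100 um, within the 32-180 um range of cross-animal glomerular
  position jitter);
* each type is present in a given OB with probability ``presence_prob``
  (default 0.9), emulating inter-OB detection variability.

Each odorant's *effective concentration threshold* for a type is the panel's
delivered concentration for that odorant, and the type's primary odorant is
its minimum-threshold (lowest-concentration) effective odorant, which the
generator constrains to belong to the type's structural class.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import OBResponse, ResponseDataset
from .odorant_panel import (
    MIXED,
    Odorant,
    OdorantPanel,
    R_GAS,
    T_DEFAULT,
    estimate_vapor_concentration,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic dataset.

    Amplitude units are dF/F in percent, so the ln-scale defaults (1.48,
    1.03) correspond to a geometric-mean response of ~4.4% dF/F.
    ``detection_noise_sd`` is an additive dF/F% noise applied per OB; 0 gives
    noise-free, bit-reproducible spectra shared across OBs.
    """

    n_mice: int = 4
    obs_per_mouse: int = 2
    n_glomeruli_per_ob: tuple[int, int] = (100, 142)
    n_odorants: int = 185
    n_classes: int = 16
    ln_amp_mean: float = 1.48
    ln_amp_sd: float = 1.03
    sparsity: float = 2.0
    single_odorant_fraction: float = 0.29
    n_diagnostic: int = 26
    presence_prob: float = 0.9
    position_jitter_sd: float = 100.0
    class_dispersion_um: float = 150.0
    uniform_classes: tuple[str, ...] = ()
    field_ml_um: tuple[float, float] = (0.0, 2000.0)
    field_ap_um: tuple[float, float] = (0.0, 2300.0)
    detection_noise_sd: float = 0.0
    mixed_fraction: float = 0.08
    same_class_cotuning: float = 0.8
    olfactometer_dilution: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mice", "obs_per_mouse", "n_odorants", "n_classes"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in (
            "ln_amp_sd", "position_jitter_sd", "detection_noise_sd",
            "class_dispersion_um",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_classes > self.n_odorants:
            raise ConfigError("n_classes may not exceed n_odorants")
        if not 0.0 <= self.single_odorant_fraction <= 1.0:
            raise ConfigError("single_odorant_fraction must lie in [0, 1]")
        if not 0.0 < self.presence_prob <= 1.0:
            raise ConfigError("presence_prob must lie in (0, 1]")

    @property
    def n_obs(self) -> int:
        return self.n_mice * self.obs_per_mouse

    @property
    def n_types(self) -> int:
        """Number of glomerulus types, set so expected per-OB counts fall in
        the configured ``n_glomeruli_per_ob`` range."""
        target = 0.5 * sum(self.n_glomeruli_per_ob)
        return max(self.n_diagnostic, int(round(target / self.presence_prob)))


@dataclass
class GroundTruth:
    """Planted tuning, amplitudes and geometry behind a synthetic dataset."""

    panel: OdorantPanel
    #: type x odorant effective-concentration thresholds (mol/L); NaN = ineffective
    tuning: pd.DataFrame
    #: type x odorant base response amplitudes (dF/F %); 0 = ineffective
    amplitudes: pd.DataFrame
    primary_odorant: pd.Series
    type_class: pd.Series
    diagnostic_flags: pd.Series
    #: per-class spatial mean (ml, ap) and dispersion (um); dispersion NaN = uniform
    class_centers: pd.DataFrame
    #: per-type home position, columns ml_um / ap_um
    type_positions: pd.DataFrame

    def __post_init__(self) -> None:
        eff = self.amplitudes.to_numpy() > 0
        if not eff.any(axis=1).all():
            raise ValueError("every glomerulus type needs >= 1 effective odorant")
        thr = self.tuning.to_numpy(dtype=float)
        cols = np.asarray(self.tuning.columns)
        argmin = np.nanargmin(np.where(eff, thr, np.inf), axis=1)
        if not (cols[argmin] == self.primary_odorant.to_numpy()).all():
            raise ValueError("primary odorant must be the minimum-threshold odorant")

    @property
    def types(self) -> list[str]:
        return list(self.tuning.index)


# --- synthetic odorant panel -------------------------------------------------

def _chain(n: int) -> str:
    return "C" * n

# (class label, SMILES builder over a small variant index)
_CLASS_TEMPLATES: list[tuple[str, object]] = [
    ("acid", lambda k: _chain(k + 2) + "(=O)O"),
    ("aldehyde", lambda k: _chain(k + 2) + "=O"),
    ("ester", lambda k: "CCOC(=O)" + _chain(k + 1)),
    ("ketone", lambda k: "CC(=O)" + _chain(k + 1)),
    ("alcohol", lambda k: _chain(k + 2) + "O"),
    ("amine", lambda k: _chain(k + 2) + "N"),
    ("thiol", lambda k: _chain(k + 1) + "S"),
    ("thioether", lambda k: "CCS" + _chain(k + 1)),
    ("pyrazine", lambda k: _chain(k + 1) + "c1cnccn1"),
    ("thiazole", lambda k: _chain(k + 1) + "c1cscn1"),
    ("aromatic aldehyde",
     lambda k: "O=Cc1ccccc1" if k == 0 else "O=Cc1ccc(" + _chain(k) + ")cc1"),
    ("aromatic ester", lambda k: _chain(k + 1) + "C(=O)Oc1ccccc1"),
    ("furan", lambda k: _chain(k + 1) + "c1ccco1"),
    ("terpenoid", [
        "CC1=CCC(CC1)C(=C)C",        # limonene
        "CC1CCC(C(C1)O)C(C)C",       # menthol
        "CC1CCC(C(C)C)C(=O)C1",      # menthone
        "CC1=CCC2CC1C2(C)C",         # alpha-pinene
        "C=C1CCC2CC1C2(C)C",         # beta-pinene
        "CC1(C)C2CCC1(C)C(=O)C2",    # camphor
        "CC1=CCC2C(C1)C2(C)C",       # 3-carene
        "CC1CCC(=C(C)C)C(=O)C1",     # pulegone
        "CC1=CCC(CC1)C(C)(C)O",      # alpha-terpineol
        "CC1=CCC(=C(C)C)CC1",        # terpinolene
        "CC12CCC(CC1)C(C)(C)O2",     # eucalyptol
        "CC1(C)C2CCC1(C)C2O",        # fenchyl alcohol
    ]),
    ("alkene", lambda k: "C=C" + _chain(k + 2)),
    ("pyridine", lambda k: _chain(k + 1) + "c1ccncc1"),
]

# genuinely mixed-feature molecules, labelled MIXED
_MIXED_SMILES = [
    "SCc1ccccc1",        # benzyl mercaptan (aromatic + thiol)
    "SCc1ccco1",         # furfuryl thiol (furan + thiol)
    "NCCc1ccccc1",       # phenethylamine (aromatic + amine)
    "CSCCC=O",           # methional (thioether + aldehyde)
    "COc1cc(C=O)ccc1O",  # vanillin (aromatic aldehyde + phenol + ether)
    "CC(=O)c1ccccc1O",   # 2'-hydroxyacetophenone (ketone + phenol)
    "O=CC=Cc1ccccc1",    # cinnamaldehyde (aromatic + enal)
    "OCCc1ccccc1",       # phenethyl alcohol (aromatic + alcohol)
    "CSc1cnccn1",        # (methylthio)pyrazine (pyrazine + thioether)
    "CC(C)CC(=O)O",      # isovaleric acid (branched acid)
    "CCC(C)C=O",         # 2-methylbutyraldehyde (branched aldehyde)
    "OCC1CCC(C)CC1",     # cyclic alcohol
]


def generate_panel(config: SimConfig, rng: np.random.Generator | None = None) -> OdorantPanel:
    """Build a synthetic odorant panel with class structure and delivered
    concentrations spanning the sub-picomolar to nanomolar range."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    classes = [name for name, _ in _CLASS_TEMPLATES[: config.n_classes]]
    n_mixed = min(len(_MIXED_SMILES), int(round(config.mixed_fraction * config.n_odorants)))
    n_classed = config.n_odorants - n_mixed
    per_class = np.full(config.n_classes, n_classed // config.n_classes)
    per_class[: n_classed % config.n_classes] += 1

    odorants: list[Odorant] = []
    for ci, (cls, template) in enumerate(_CLASS_TEMPLATES[: config.n_classes]):
        prefix = chr(ord("A") + ci)
        for k in range(per_class[ci]):
            if isinstance(template, list):
                smiles = template[k % len(template)]
            else:
                smiles = template(k)
            odorants.append(_make_odorant(
                f"{prefix}{k + 1:02d}", f"{cls} {k + 1}", cls, smiles, config, rng))
    for k in range(n_mixed):
        odorants.append(_make_odorant(
            f"X{k + 1:02d}", f"mixed {k + 1}", MIXED, _MIXED_SMILES[k], config, rng))
    return OdorantPanel(odorants, class_order=classes)


def _make_odorant(
    oid: str, name: str, cls: str, smiles: str, config: SimConfig,
    rng: np.random.Generator,
) -> Odorant:
    # target delivered concentration: lognormal around 1e-10 M, clipped to the
    # 4e-14 .. 4e-9 M screening range
    conc = float(np.clip(10 ** rng.normal(-10.0, 0.75), 4e-14, 4e-9))
    vp = float(10 ** rng.normal(1.5, 1.0))  # Pa
    x = conc * 1000.0 * R_GAS * T_DEFAULT / (vp * config.olfactometer_dilution)
    x = min(x, 1.0)
    est = estimate_vapor_concentration(vp, x, config.olfactometer_dilution)
    return Odorant(
        id=oid, name=name, structural_class=cls, smiles=smiles,
        vapor_pressure=vp, liquid_mole_fraction=x, est_concentration=est,
    )


# --- ground truth ------------------------------------------------------------

def _breadth_rate(config: SimConfig) -> float:
    """Poisson rate for extra co-tuned odorants, calibrated so the expected
    number of responsive types per odorant matches the sparsity target."""
    f = config.single_odorant_fraction
    mean_breadth = config.sparsity * config.n_odorants / config.n_types
    if f >= 1.0:
        return 0.0
    return max(0.0, (mean_breadth - f) / (1.0 - f) - 2.0)


def generate_ground_truth(
    config: SimConfig, panel: OdorantPanel | None = None
) -> GroundTruth:
    rng = np.random.default_rng(config.seed)
    if panel is None:
        panel = generate_panel(config, rng)
    ids = panel.ids
    conc = pd.Series({o.id: o.est_concentration for o in panel})
    cls_of = pd.Series(panel.classes)
    classes = panel.class_order

    n_types = config.n_types
    type_ids = [f"g{t:03d}" for t in range(n_types)]
    # assign types to classes round-robin over a shuffled class order so
    # every class hosts types
    cls_cycle = list(classes)
    rng.shuffle(cls_cycle)
    type_cls = [cls_cycle[t % len(cls_cycle)] for t in range(n_types)]

    by_class: dict[str, list[str]] = {
        c: [o for o in ids if cls_of[o] == c] for c in classes
    }

    # exclusive diagnostic odorants, one per diagnostic type, spread over classes
    diag_flags = np.zeros(n_types, dtype=bool)
    diag_flags[: config.n_diagnostic] = True
    reserved: dict[int, str] = {}
    taken: set[str] = set()
    for t in range(min(config.n_diagnostic, n_types)):
        pool = [o for o in by_class[type_cls[t]] if o not in taken]
        if not pool:
            pool = [o for o in ids if o not in taken and cls_of[o] != MIXED]
            type_cls[t] = cls_of[pool[0]] if pool else type_cls[t]
        choice = pool[rng.integers(len(pool))]
        reserved[t] = choice
        taken.add(choice)

    lam = _breadth_rate(config)
    amp = np.zeros((n_types, len(ids)))
    thr = np.full((n_types, len(ids)), np.nan)
    primaries: list[str] = []
    col = {o: j for j, o in enumerate(ids)}
    conc_arr = conc.to_numpy()

    for t in range(n_types):
        cls = type_cls[t]
        effective: list[str]
        if rng.random() < config.single_odorant_fraction:
            n_extra = 0
        else:
            n_extra = 1 + rng.poisson(lam)  # breadth = 2 + Poisson incl. primary
        if t in reserved:
            # diagnostic type: its exclusive odorant stays the most sensitive
            primary = reserved[t]
            effective = [primary]
            p_conc = conc[primary]
            eligible_same = [
                o for o in by_class[cls]
                if conc[o] > p_conc and o not in taken
            ]
            eligible_any = [
                o for o in ids if conc[o] > p_conc and o not in taken
            ]
            for _ in range(n_extra):
                same = eligible_same and rng.random() < config.same_class_cotuning
                pool = [o for o in (eligible_same if same else eligible_any)
                        if o not in effective]
                if not pool:
                    pool = [o for o in eligible_any if o not in effective]
                if not pool:
                    break
                effective.append(pool[rng.integers(len(pool))])
        else:
            # class-first draw: same-class odorants unconstrained, cross-class
            # odorants only above the class members' minimum concentration, so
            # the primary (minimum threshold) stays within the type's class
            in_class = [o for o in by_class[cls] if o not in taken]
            n_same = 1 + rng.binomial(n_extra, config.same_class_cotuning)
            n_same = min(n_same, len(in_class))
            chosen = list(rng.choice(in_class, size=n_same, replace=False))
            cmin = min(conc[o] for o in chosen)
            eligible_out = [
                o for o in ids
                if conc[o] > cmin and o not in taken and o not in chosen
            ]
            n_out = min(1 + n_extra - n_same, len(eligible_out))
            if n_out > 0:
                chosen += list(rng.choice(eligible_out, size=n_out, replace=False))
            effective = chosen
            primary = min(effective, key=lambda o: conc[o])
        primaries.append(primary)
        for o in effective:
            j = col[o]
            amp[t, j] = np.exp(rng.normal(config.ln_amp_mean, config.ln_amp_sd))
            thr[t, j] = conc_arr[j]

    # spatial layout: class centers inside an inner margin of the field
    ml_lo, ml_hi = config.field_ml_um
    ap_lo, ap_hi = config.field_ap_um
    margin = 0.15
    centers = {}
    for c in classes:
        cx = rng.uniform(ml_lo + margin * (ml_hi - ml_lo), ml_hi - margin * (ml_hi - ml_lo))
        cy = rng.uniform(ap_lo + margin * (ap_hi - ap_lo), ap_hi - margin * (ap_hi - ap_lo))
        disp = np.nan if c in config.uniform_classes else config.class_dispersion_um
        centers[c] = (cx, cy, disp)
    class_centers = pd.DataFrame(
        centers, index=["ml_um", "ap_um", "dispersion_um"]
    ).T

    pos = np.empty((n_types, 2))
    for t in range(n_types):
        cx, cy, disp = centers[type_cls[t]]
        if np.isnan(disp):
            pos[t] = (rng.uniform(ml_lo, ml_hi), rng.uniform(ap_lo, ap_hi))
        else:
            pos[t] = (
                np.clip(rng.normal(cx, disp), ml_lo, ml_hi),
                np.clip(rng.normal(cy, disp), ap_lo, ap_hi),
            )

    return GroundTruth(
        panel=panel,
        tuning=pd.DataFrame(thr, index=type_ids, columns=ids),
        amplitudes=pd.DataFrame(amp, index=type_ids, columns=ids),
        primary_odorant=pd.Series(primaries, index=type_ids),
        type_class=pd.Series(type_cls, index=type_ids),
        diagnostic_flags=pd.Series(diag_flags, index=type_ids),
        class_centers=class_centers,
        type_positions=pd.DataFrame(pos, index=type_ids, columns=["ml_um", "ap_um"]),
    )


# --- response matrices -------------------------------------------------------

def generate_responses(truth: GroundTruth, config: SimConfig) -> ResponseDataset:
    """Realize per-OB response matrices and glomerulus positions.

    Each type is present in an OB with probability ``presence_prob``; present
    types inherit the type's base amplitudes (identical across OBs) plus
    optional additive detection noise, and its home position plus Gaussian
    positional jitter.  Row order is shuffled per OB so algorithms cannot
    rely on row alignment across OBs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ids = truth.panel.ids
    n_types = len(truth.types)
    base = truth.amplitudes.to_numpy()
    homes = truth.type_positions.to_numpy()
    obs = []
    for m in range(config.n_mice):
        for s in range(config.obs_per_mouse):
            side = chr(ord("L") + s) if config.obs_per_mouse <= 2 else f"s{s}"
            ob_id = f"m{m + 1}{side}"
            present = rng.random(n_types) < config.presence_prob
            idx = np.flatnonzero(present)
            rng.shuffle(idx)
            mat = base[idx].copy()
            if config.detection_noise_sd > 0:
                mat = mat + rng.normal(0.0, config.detection_noise_sd, mat.shape)
                mat[mat < 3.0 * config.detection_noise_sd] = 0.0
            jitter = rng.normal(0.0, config.position_jitter_sd, (len(idx), 2))
            pos = homes[idx] + jitter
            pos[:, 0] = np.clip(pos[:, 0], *config.field_ml_um)
            pos[:, 1] = np.clip(pos[:, 1], *config.field_ap_um)
            gids = [truth.types[i] for i in idx]
            obs.append(
                OBResponse(
                    responses=pd.DataFrame(mat, index=gids, columns=ids),
                    positions=pd.DataFrame(pos, index=gids, columns=["ml_um", "ap_um"]),
                    ob_id=ob_id,
                    mouse_id=f"m{m + 1}",
                    baseline_f=pd.Series(
                        np.exp(rng.normal(np.log(100.0), 0.2, len(idx))), index=gids
                    ),
                )
            )
    return ResponseDataset(obs)


# --- synthetic image stacks --------------------------------------------------

def generate_image_stack(
    truth: GroundTruth,
    config: SimConfig,
    odorant: str,
    *,
    shape: tuple[int, int] = (256, 256),
    frame_rate: float = 25.0,
    duration_s: float = 6.0,
    onset_s: float = 2.0,
    n_trials: int = 3,
    baseline: float = 100.0,
    focus_sigma_px: float = 3.0,
    pixel_noise_sd: float = 0.0,
    decay_tau_s: float | None = None,
    rng: np.random.Generator | None = None,
):
    """Render a trial-resolved fluorescence stack for one odorant.

    Static baseline plus 2-D Gaussian foci at the home positions of the
    types effective for the odorant.  Focus amplitude (peak dF) equals the
    type's base amplitude and follows a step time course beginning at odorant
    onset (an exponential decay with time constant ``decay_tau_s`` can be
    superimposed), plus i.i.d. Gaussian pixel noise.
    """
    from .signal_extraction import TrialStack

    if odorant not in truth.panel.ids:
        raise KeyError(f"odorant {odorant!r} not in panel")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    h, w = shape
    n_frames = int(round(duration_s * frame_rate))
    t = np.arange(n_frames) / frame_rate
    course = (t >= onset_s).astype(float)
    if decay_tau_s is not None:
        course *= np.exp(-np.clip(t - onset_s, 0.0, None) / decay_tau_s)

    ml_lo, ml_hi = config.field_ml_um
    ap_lo, ap_hi = config.field_ap_um
    amps = truth.amplitudes[odorant]
    df_image = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for tid, a in amps[amps > 0].items():
        ml, ap = truth.type_positions.loc[tid]
        cx = (ml - ml_lo) / (ml_hi - ml_lo) * (w - 1)
        cy = (ap - ap_lo) / (ap_hi - ap_lo) * (h - 1)
        df_image += a * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * focus_sigma_px**2)
        )

    frames = baseline + course[None, :, None, None] * df_image[None, None, :, :]
    frames = np.broadcast_to(frames, (n_trials, n_frames, h, w)).astype(np.float32).copy()
    if pixel_noise_sd > 0:
        frames += rng.normal(0.0, pixel_noise_sd, frames.shape).astype(np.float32)
    return TrialStack(
        frames=frames, frame_rate=frame_rate, odor_onset=onset_s, trial_count=n_trials
    )


# --- serialization -----------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize ground truth as JSON (panel excluded; write it separately)."""
    payload = {
        "tuning": truth.tuning.where(truth.tuning.notna(), None).to_dict(orient="split"),
        "amplitudes": truth.amplitudes.to_dict(orient="split"),
        "primary_odorant": truth.primary_odorant.to_dict(),
        "type_class": truth.type_class.to_dict(),
        "diagnostic_flags": {k: bool(v) for k, v in truth.diagnostic_flags.items()},
        "class_centers": truth.class_centers.to_dict(orient="split"),
        "type_positions": truth.type_positions.to_dict(orient="split"),
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")
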