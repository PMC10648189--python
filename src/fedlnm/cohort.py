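"""Seeded synthetic cohorts emulating a two-center gynecologic-oncology LNM study.

The real study population (567 patients: 423 cervical carcinoma at 21.04%
nodal-metastasis prevalence, 144 endometrial carcinoma at 9.72%) is private, so
every downstream stage of the pipeline runs on cohorts drawn here. The
generator reproduces the cohort's *published structure* exactly:

* positive counts are exact quotas ``round(n * prevalence)`` per diagnosis, so
  the headline counts are deterministic regression anchors, not random draws;
* per-modality reader calls (CT / MRI / PET-CT) are Bernoulli at the published
  per-modality sensitivity and specificity, optionally correlated across
  modalities through a shared latent "nodal conspicuity" per patient;
* clinical covariates follow the published marginal category frequencies;
* which patients receive which scan follows independent per-modality coverage
  probabilities fitted to the published examination-group sizes;
* an optional logistic link plants covariate->LNM signal (used by the
  federated-learning presets) while keeping positive quotas exact, via a
  Gumbel-race weighted draw without replacement.

MRI appearance is emulated by 64x64 grayscale phantoms: smooth background
texture plus, for node-positive cases, one bright elliptical blob whose support
is the ground-truth segmentation mask.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .exceptions import ConfigurationError, QuotaError

__all__ = [
    "CohortConfig",
    "ImageConfig",
    "PatientRecord",
    "SyntheticImage",
    "ClientDataset",
    "generate_cohort",
    "generate_image",
    "generate_images",
    "partition_clients",
    "split_train_test",
    "encode_features",
    "feature_names",
    "epidemiologic_config",
    "federated_config",
    "external_oc_config",
    "MODALITIES",
    "TABLE3_QUOTAS",
]

MODALITIES = ("CT", "MRI", "PET/CT")

# Published per-modality operating points (sensitivity, specificity).
DEFAULT_OPERATING_POINTS: dict[str, tuple[float, float]] = {
    "CT": (0.3263, 0.9215),
    "MRI": (0.3590, 0.9337),
    "PET/CT": (0.5769, 0.8571),
}

# Examination-group sizes out of 567 -> independent per-modality coverage.
DEFAULT_COVERAGE: dict[str, float] = {
    "CT": 439 / 567,
    "MRI": 440 / 567,
    "PET/CT": 393 / 567,
}

# Default two-client composition: (n positive, n negative) per client.
TABLE3_QUOTAS: dict[int, tuple[int, int]] = {0: (111, 115), 1: (226, 115)}

# Published marginal category frequencies, per diagnosis. Counts are used as
# sampling weights (some published columns do not sum exactly to n).
_CC_FIGO = (("IA1", 8), ("IA2", 18), ("IB1", 219), ("IB2", 33), ("IIA1", 61), ("IIA2", 84))
_EC_FIGO = (("IA", 102), ("IB", 18), ("II", 6), ("IIIA", 4), ("IIIC1", 9), ("IIIC2", 5))
_CC_STROMAL = (("<1/3", 171), ("1/3-2/3", 86), (">2/3", 166))
_EC_STROMAL = (("<1/2", 117), (">1/2", 27))
_CC_HIST = (("squamous", 321), ("adenocarcinoma", 81), ("adenosquamous", 8),
            ("neuroendocrine", 9), ("clear_cell", 1), ("rhabdomyosarcoma", 1),
            ("carcinosarcoma", 1), ("wart_like", 1))
_EC_HIST = (("endometrioid", 131), ("clear_cell", 6), ("serous", 4), ("carcinosarcoma", 3))
_CC_GRADE = (("1", 10), ("2", 197), ("3", 70), ("nk_scc", 26), ("k_scc", 5), ("not_reported", 91))
_EC_GRADE = (("1", 33), ("2", 64), ("3", 26), ("not_reported", 8))
_LVSI_RATE = {"CC": 113 / 423, "EC": 21 / 144}

_HIGH_RISK_HIST = frozenset(
    {"neuroendocrine", "clear_cell", "serous", "carcinosarcoma", "rhabdomyosarcoma"})
_FIGO_ORDER = {
    "CC": {lvl: i for i, (lvl, _) in enumerate(_CC_FIGO)},
    "EC": {lvl: i for i, (lvl, _) in enumerate(_EC_FIGO)},
}
_STROMAL_SCORE = {"<1/3": 0.0, "1/3-2/3": 0.5, ">2/3": 1.0, "<1/2": 0.0, ">1/2": 1.0}
_GRADE_SCORE = {"1": 0.0, "2": 0.5, "3": 1.0, "nk_scc": 0.5, "k_scc": 0.5, "not_reported": 0.5}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Child generator at a fixed offset of the master seed."""
    return np.random.default_rng([int(seed), int(stream)])


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort draw."""

    n_cc: int = 423
    n_ec: int = 144
    prevalence_cc: float = 0.2104
    prevalence_ec: float = 0.0972
    modality_operating_points: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OPERATING_POINTS))
    modality_coverage: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVERAGE))
    age_range: tuple[int, int] = (19, 78)
    age_median: float = 49.0
    age_sd: float = 12.0
    conspicuity: float = 0.0  # shared-latent correlation of calls, in [0, 1)
    signal_coefficients: Mapping[str, float] | None = None  # covariate->LNM logistic link
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cc < 0 or self.n_ec < 0:
            raise ConfigurationError("cohort sizes must be non-negative")
        for name, p in (("prevalence_cc", self.prevalence_cc),
                        ("prevalence_ec", self.prevalence_ec)):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        for m, cov in self.modality_coverage.items():
            if m not in self.modality_operating_points:
                raise ConfigurationError(f"modality {m!r} has coverage but no operating point")
            if not 0.0 <= cov <= 1.0:
                raise ConfigurationError(f"coverage for {m!r} outside [0, 1]")
        for m, (se, sp) in self.modality_operating_points.items():
            if not (0.0 <= se <= 1.0 and 0.0 <= sp <= 1.0):
                raise ConfigurationError(f"operating point for {m!r} outside [0, 1]^2")
        if not 0.0 <= self.conspicuity < 1.0:
            raise ConfigurationError("conspicuity must lie in [0, 1)")

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(self.modality_operating_points)


@dataclass(frozen=True)
class ImageConfig:
    """Parameters of the MRI-like phantom generator."""

    height: int = 64
    width: int = 64
    contrast: float = 0.35            # blob peak intensity above background
    noise: float = 0.06               # background texture amplitude
    background_level: float = 0.35
    smooth_sigma: float = 2.0         # texture correlation length (pixels)
    min_axis: float = 3.0             # ellipse semi-axes (pixels)
    max_axis: float = 6.0
    hard_negative_rate: float = 0.2   # negatives that get a sub-threshold blob
    hard_negative_contrast: float = 0.25  # fraction of full contrast
    min_blob_area: int = 20           # guaranteed mask pixels for positives
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ConfigurationError("image dimensions must be positive")
        if not 0.0 <= self.hard_negative_rate <= 1.0:
            raise ConfigurationError("hard_negative_rate outside [0, 1]")
        if self.min_axis <= 0 or self.max_axis < self.min_axis:
            raise ConfigurationError("require 0 < min_axis <= max_axis")


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient."""

    patient_id: str
    diagnosis: str                    # "CC" or "EC"
    age: int
    figo_stage: str
    lvsi: bool
    stromal_invasion: str
    histology: str
    grade: str
    true_lnm: bool
    calls: Mapping[str, str]          # modality -> positive | negative | not_performed
    image_id: str | None = None


@dataclass(frozen=True)
class SyntheticImage:
    """2-D grayscale phantom with its nodal-region mask."""

    pixels: np.ndarray                # float in [0, 1], shape (H, W)
    mask: np.ndarray                  # bool, same shape; nonempty iff label
    label: bool

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ClientDataset:
    """One simulated data-holding institution."""

    client_id: int
    records: list[PatientRecord]
    images: dict[str, SyntheticImage] = field(default_factory=dict)
    train_ids: tuple[str, ...] = ()
    test_ids: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return len(self.records)

    def record_ids(self) -> tuple[str, ...]:
        return tuple(r.patient_id for r in self.records)

    def subset(self, ids: Iterable[str]) -> list[PatientRecord]:
        wanted = set(ids)
        return [r for r in self.records if r.patient_id in wanted]


def _sample_categorical(rng: np.random.Generator, table: Sequence[tuple[str, int]],
                        size: int) -> np.ndarray:
    labels = np.array([t[0] for t in table])
    w = np.array([t[1] for t in table], dtype=float)
    return rng.choice(labels, size=size, p=w / w.sum())


def _sample_ages(rng: np.random.Generator, cfg: CohortConfig, size: int) -> np.ndarray:
    a = rng.normal(cfg.age_median, cfg.age_sd, size=size)
    lo, hi = cfg.age_range
    return np.clip(np.rint(a), lo, hi).astype(int)


def feature_names(modalities: Sequence[str] = MODALITIES) -> list[str]:
    """Column names of the encoded feature matrix, covariates first."""
    base = ["is_ec", "age_z", "figo", "lvsi", "stromal", "grade", "hist_highrisk"]
    return base + [f"call_{m}" for m in modalities]


def encode_features(records: Sequence[PatientRecord],
                    modalities: Sequence[str] = MODALITIES,
                    include_calls: bool = True) -> np.ndarray:
    """Encode records as a numeric matrix for the text model.

    Ordinal covariates are scaled to [0, 1]; age is standardised around the
    cohort median; each modality contributes one column in {+1, -1, 0} for
    positive / negative / not performed.
    """
    n = len(records)
    cols = feature_names(modalities)
    X = np.zeros((n, len(cols)), dtype=float)
    for i, r in enumerate(records):
        order = _FIGO_ORDER[r.diagnosis]
        X[i, 0] = 1.0 if r.diagnosis == "EC" else 0.0
        X[i, 1] = (r.age - 49.0) / 12.0
        X[i, 2] = order[r.figo_stage] / max(len(order) - 1, 1)
        X[i, 3] = 1.0 if r.lvsi else 0.0
        X[i, 4] = _STROMAL_SCORE[r.stromal_invasion]
        X[i, 5] = _GRADE_SCORE[r.grade]
        X[i, 6] = 1.0 if r.histology in _HIGH_RISK_HIST else 0.0
        if include_calls:
            for j, m in enumerate(modalities):
                call = r.calls.get(m, "not_performed")
                X[i, 7 + j] = {"positive": 1.0, "negative": -1.0}.get(call, 0.0)
    return X


def _plant_positives(rng: np.random.Generator, eta: np.ndarray, n_pos: int) -> np.ndarray:
    """Choose exactly n_pos positives, weighted by exp(eta) (Gumbel race)."""
    n = eta.shape[0]
    flag = np.zeros(n, dtype=bool)
    if n_pos <= 0:
        return flag
    keys = eta + rng.gumbel(size=n)
    flag[np.argsort(keys)[::-1][:n_pos]] = True
    return flag


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Draw one cohort. Deterministic given ``config.seed``.

    Positive counts are exact quotas ``round(n * prevalence)`` per diagnosis.
    Performed reader calls are Bernoulli at the modality's sensitivity
    (node-positive patients) or 1 - specificity (node-negative), optionally
    correlated across modalities through the shared conspicuity latent.
    """
    groups = (("CC", config.n_cc, config.prevalence_cc),
              ("EC", config.n_ec, config.prevalence_ec))
    rng_cov = _rng(config.seed, 0)
    rng_lnm = _rng(config.seed, 1)
    rng_call = _rng(config.seed, 2)
    rng_scan = _rng(config.seed, 3)

    records: list[PatientRecord] = []
    idx = 0
    for diag, n, prev in groups:
        if n == 0:
            continue
        figo = _sample_categorical(rng_cov, _CC_FIGO if diag == "CC" else _EC_FIGO, n)
        stromal = _sample_categorical(rng_cov, _CC_STROMAL if diag == "CC" else _EC_STROMAL, n)
        hist = _sample_categorical(rng_cov, _CC_HIST if diag == "CC" else _EC_HIST, n)
        grade = _sample_categorical(rng_cov, _CC_GRADE if diag == "CC" else _EC_GRADE, n)
        lvsi = rng_cov.random(n) < _LVSI_RATE[diag]
        ages = _sample_ages(rng_cov, config, n)

        draft = [PatientRecord(
            patient_id=f"P{idx + i:04d}", diagnosis=diag, age=int(ages[i]),
            figo_stage=str(figo[i]), lvsi=bool(lvsi[i]), stromal_invasion=str(stromal[i]),
            histology=str(hist[i]), grade=str(grade[i]), true_lnm=False, calls={})
            for i in range(n)]

        n_pos = _round_half_up(n * prev)
        if config.signal_coefficients:
            Xc = encode_features(draft, config.modalities, include_calls=False)
            names = feature_names(config.modalities)
            beta = np.array([config.signal_coefficients.get(c, 0.0) for c in names])
            eta = Xc @ beta
        else:
            eta = np.zeros(n)
        pos = _plant_positives(rng_lnm, eta, n_pos)

        # Shared latent nodal conspicuity drives inter-modality call correlation
        # while leaving each modality's marginal operating point exact.
        rho = config.conspicuity
        z = rng_call.normal(size=n)
        calls_by_mod: dict[str, np.ndarray] = {}
        performed_by_mod: dict[str, np.ndarray] = {}
        for m in config.modalities:
            se, sp = config.modality_operating_points[m]
            p = np.where(pos, se, 1.0 - sp)
            u = rho * z + math.sqrt(1.0 - rho * rho) * rng_call.normal(size=n)
            calls_by_mod[m] = u < norm.ppf(p)
            cov = config.modality_coverage.get(m, 1.0)
            performed_by_mod[m] = rng_scan.random(n) < cov

        for i, rec in enumerate(draft):
            calls = {}
            for m in config.modalities:
                if not performed_by_mod[m][i]:
                    calls[m] = "not_performed"
                else:
                    calls[m] = "positive" if calls_by_mod[m][i] else "negative"
            records.append(replace(rec, true_lnm=bool(pos[i]), calls=calls))
        idx += n
    return records


def generate_image(record: PatientRecord, image_config: ImageConfig | Mapping | None = None
                   ) -> SyntheticImage:
    """Render the MRI-like phantom for one patient.

    Node-positive cases get one bright elliptical blob whose geometric support
    is the mask; with probability ``hard_negative_rate`` a node-negative case
    gets a faint sub-threshold blob (mask stays empty). Deterministic given the
    config seed and the patient id.
    """
    if image_config is None:
        cfg = ImageConfig()
    elif isinstance(image_config, ImageConfig):
        cfg = image_config
    else:
        cfg = ImageConfig(**dict(image_config))
    tag = zlib.crc32(record.patient_id.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng([int(cfg.seed), 4, tag])

    h, w = cfg.height, cfg.width
    texture = gaussian_filter(rng.normal(size=(h, w)), cfg.smooth_sigma)
    sd = texture.std()
    if sd > 0:
        texture /= sd
    pixels = cfg.background_level + cfg.noise * texture
    mask = np.zeros((h, w), dtype=bool)

    draw_blob = record.true_lnm
    amplitude = cfg.contrast
    if not record.true_lnm and rng.random() < cfg.hard_negative_rate:
        draw_blob = True
        amplitude = cfg.contrast * cfg.hard_negative_contrast
    if draw_blob:
        a = rng.uniform(cfg.min_axis, cfg.max_axis)
        b = rng.uniform(cfg.min_axis, cfg.max_axis)
        theta = rng.uniform(0.0, math.pi)
        margin = cfg.max_axis + 2.0
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        yy, xx = np.mgrid[0:h, 0:w]
        dy, dx = yy - cy, xx - cx
        u = dx * math.cos(theta) + dy * math.sin(theta)
        v = -dx * math.sin(theta) + dy * math.cos(theta)
        r2 = (u / a) ** 2 + (v / b) ** 2
        # quartic falloff: a sharp visible edge near the mask boundary (r2 = 1),
        # so the annotated support coincides with the visibly bright region
        pixels = pixels + amplitude * np.exp(-r2 * r2)
        if record.true_lnm:
            mask = r2 <= 1.0

    return SyntheticImage(pixels=np.clip(pixels, 0.0, 1.0), mask=mask,
                          label=bool(record.true_lnm))


def generate_images(records: Sequence[PatientRecord],
                    image_config: ImageConfig | None = None
                    ) -> tuple[list[PatientRecord], dict[str, SyntheticImage]]:
    """Attach one phantom per record; returns updated records and the image map."""
    cfg = image_config or ImageConfig()
    out_records, images = [], {}
    for rec in records:
        img_id = f"img_{rec.patient_id}"
        images[img_id] = generate_image(rec, cfg)
        out_records.append(replace(rec, image_id=img_id))
    return out_records, images


def partition_clients(cohort: Sequence[PatientRecord],
                      quotas: Mapping[int, tuple[int, int]] | None = None,
                      seed: int = 0) -> tuple[ClientDataset, ClientDataset]:
    """Split a cohort into two clients with fixed positive/negative quotas.

    Default quotas follow the published client composition
    (client 0: 111+/115-, client 1: 226+/115-). Assignment within a class is a
    seeded shuffle; records beyond the quotas are left unassigned.
    """
    q = dict(quotas) if quotas is not None else dict(TABLE3_QUOTAS)
    if set(q) != {0, 1}:
        raise ConfigurationError("quotas must cover exactly clients 0 and 1")
    rng = _rng(seed, 10)
    pos = [r for r in cohort if r.true_lnm]
    neg = [r for r in cohort if not r.true_lnm]
    need_pos = q[0][0] + q[1][0]
    need_neg = q[0][1] + q[1][1]
    if len(pos) < need_pos:
        raise QuotaError(f"need {need_pos} positive records, cohort has {len(pos)} "
                         f"(short by {need_pos - len(pos)})")
    if len(neg) < need_neg:
        raise QuotaError(f"need {need_neg} negative records, cohort has {len(neg)} "
                         f"(short by {need_neg - len(neg)})")
    pos = [pos[i] for i in rng.permutation(len(pos))]
    neg = [neg[i] for i in rng.permutation(len(neg))]

    clients = []
    p0 = n0 = 0
    for cid in (0, 1):
        np_, nn_ = q[cid]
        recs = pos[p0:p0 + np_] + neg[n0:n0 + nn_]
        p0 += np_
        n0 += nn_
        clients.append(ClientDataset(client_id=cid, records=recs))
    return clients[0], clients[1]


def split_train_test(client: ClientDataset, ratio: float = 0.8, seed: int = 0) -> ClientDataset:
    """Class-stratified train/test split with ``train = round(ratio * n)``.

    Per-class train counts are rounded half-up, then the total is reconciled to
    ``round(ratio * n)`` by adjusting the larger class. Returns a new
    ClientDataset with ``train_ids`` / ``test_ids`` filled.
    """
    if not 0.0 < ratio < 1.0:
        raise ConfigurationError(f"ratio={ratio} outside (0, 1)")
    rng = _rng(seed, 20 + client.client_id)
    pos = [r.patient_id for r in client.records if r.true_lnm]
    neg = [r.patient_id for r in client.records if not r.true_lnm]
    pos = [pos[i] for i in rng.permutation(len(pos))]
    neg = [neg[i] for i in rng.permutation(len(neg))]

    target_total = _round_half_up(ratio * client.n)
    n_tr = {"pos": _round_half_up(ratio * len(pos)), "neg": _round_half_up(ratio * len(neg))}
    larger = "pos" if len(pos) >= len(neg) else "neg"
    n_tr[larger] += target_total - (n_tr["pos"] + n_tr["neg"])

    train = pos[:n_tr["pos"]] + neg[:n_tr["neg"]]
    test = pos[n_tr["pos"]:] + neg[n_tr["neg"]:]
    return ClientDataset(client_id=client.client_id, records=list(client.records),
                         images=dict(client.images),
                         train_ids=tuple(train), test_ids=tuple(test))


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: Covariate->LNM logistic link of the planted-signal presets. Coefficients act
#: on the encoded feature scale (each column roughly unit range); they make
#: nodal status strongly predictable from stage, invasion depth and LVSI, so a
#: correctly trained text model can recover a high AUC.
PLANTED_SIGNAL = {
    "lvsi": 5.0,
    "figo": 4.0,
    "stromal": 3.0,
    "age_z": 2.0,
    "hist_highrisk": 2.0,
}


def epidemiologic_config(seed: int = 0) -> CohortConfig:
    """Cohort faithful to the published epidemiology: 21.04% / 9.72% prevalence,
    published scan coverage, no planted covariate signal."""
    return CohortConfig(seed=seed)


def federated_config(seed: int = 0) -> CohortConfig:
    """Cohort matching the published client partition (337 positives of 567),
    full modality coverage and planted covariate signal for model training."""
    return CohortConfig(
        prevalence_cc=0.5944, prevalence_ec=0.5944,
        modality_coverage={m: 1.0 for m in MODALITIES},
        signal_coefficients=dict(PLANTED_SIGNAL),
        seed=seed,
    )


def external_oc_config(seed: int = 0, n: int = 115) -> CohortConfig:
    """Ovarian-cancer-like external validation preset: a smaller, older cohort
    with shifted prevalence, full coverage and the same planted signal."""
    return CohortConfig(
        n_cc=0, n_ec=n, prevalence_ec=0.40,
        age_median=56.0,
        modality_coverage={m: 1.0 for m in MODALITIES},
        signal_coefficients=dict(PLANTED_SIGNAL),
        seed=seed,
    )
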