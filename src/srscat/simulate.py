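"""Synthetic study generator.

Emulates the two-site, three-arm validation design: a clinical site whose
referred children are mostly autistic (~84% ASD, 72% male, mostly preschool
forms) and a general-population site (~2% ASD, 34% male, school-age forms),
with enrollees block-randomized to full (65-item), short (16-item) or
adaptive administrations.  Latent traits are site/sex baselines plus a
case shift of 2 latent SD, responses follow the graded response model, and
at the general-population site the shortened arms also complete the
"remaining" items so within-person full totals exist.

True item parameters live in a separate truth record that analysis code never
reads; they are exposed only to oracle tests.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .bank import ItemBank, ItemParameters
from .cat import CATConfig, administer, simulated_provider
from .errors import SrsCatError
from .irt import _cumulative

__all__ = [
    "StudyDesign",
    "SyntheticBankSpec",
    "SimulatedStudy",
    "generate_bank",
    "generate_respondents",
    "generate_responses",
    "simulate_study",
    "make_fixture",
    "FIXTURE_PRESETS",
    "group_label",
]

ARMS = ("full", "short", "cat")
SITES = ("clinical", "general")


def group_label(form: str, sex: str) -> str:
    """Calibration-group key combining form and sex."""
    return f"{form}|{sex}"


@dataclass(frozen=True)
class StudyDesign:
    """Study-level margins.

    Sample sizes, per-site ASD prevalence and sex ratios follow the two-site
    design (154 clinical / 201 general; 84% vs 2% ASD; 72% vs 34% male).
    ``case_shift`` is the ASD vs non-ASD latent separation in residual-SD
    units (default 2); site-level score differences then emerge from the case
    mix rather than being imposed.  A positive clinical baseline can model
    referral skew (referred non-cases with elevated traits) but is off by
    default so the configured case/non-case separation is what the data show.
    """

    n_clinical: int = 154
    n_general: int = 201
    p_asd_clinical: float = 0.84
    p_asd_general: float = 0.02
    p_male_clinical: float = 0.72
    p_male_general: float = 0.34
    p_preschool_clinical: float = 0.63
    p_preschool_general: float = 0.005
    arms: tuple[str, ...] = ARMS
    theta_baseline_clinical: float = 0.0
    theta_baseline_general: float = 0.0
    male_shift: float = 0.15
    case_shift: float = 2.0
    theta_sd: float = 1.0
    remaining_items_protocol: bool = True  # general site only
    two_arm_first_n: int = 0  # enrollees randomized full/short only (pre-CAT period)
    seed: int | None = None

    def __post_init__(self):
        for name in (
            "p_asd_clinical", "p_asd_general",
            "p_male_clinical", "p_male_general",
            "p_preschool_clinical", "p_preschool_general",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise SrsCatError(f"{name} must lie in [0, 1], got {p}")
        if self.n_clinical < 0 or self.n_general < 0:
            raise SrsCatError("sample sizes must be non-negative")
        if self.theta_sd <= 0:
            raise SrsCatError("theta_sd must be positive")


@dataclass(frozen=True)
class SyntheticBankSpec:
    """Stand-in item-bank generator for a 65-item, 4-category instrument.

    Discriminations are log-normal around a median of 1.5; item locations
    spread over the latent range with most mass above the general-population
    mean (low scores are typical there); thresholds sit at location -/+ a
    positive spacing so they are strictly increasing by construction.  The
    short form takes the 16 most discriminating items, mirroring how short
    forms select high-loading items.  ``dif_sd`` adds group-specific
    threshold offsets (differential item functioning) for each label in
    ``groups``.
    """

    n_items: int = 65
    n_categories: int = 4
    discrimination_median: float = 1.5
    discrimination_sigma: float = 0.3
    center_mean: float = 0.75
    center_sd: float = 0.9
    spacing_low: float = 0.5
    spacing_high: float = 1.0
    short_size: int = 16
    reverse_size: int = 0
    dif_sd: float = 0.0
    groups: tuple[str, ...] = ()

    def __post_init__(self):
        if self.short_size > self.n_items:
            raise SrsCatError("short_size cannot exceed n_items")
        if self.reverse_size > self.n_items:
            raise SrsCatError("reverse_size cannot exceed n_items")
        if self.spacing_low <= 0 or self.spacing_high < self.spacing_low:
            raise SrsCatError("need 0 < spacing_low <= spacing_high")
        if self.n_categories < 2:
            raise SrsCatError("need at least 2 response categories")
        if self.dif_sd > 0 and not self.groups:
            raise SrsCatError("dif_sd > 0 requires group labels")


def generate_bank(
    spec: SyntheticBankSpec | None = None, seed: int | None = None
) -> tuple[ItemBank, dict]:
    """Reproducible synthetic bank plus a truth record of every parameter."""
    spec = spec or SyntheticBankSpec()
    rng = np.random.default_rng(seed)
    n, kk = spec.n_items, spec.n_categories - 1
    a = np.exp(
        np.log(spec.discrimination_median)
        + spec.discrimination_sigma * rng.standard_normal(n)
    )
    centers = spec.center_mean + spec.center_sd * rng.standard_normal(n)
    spacings = rng.uniform(spec.spacing_low, spec.spacing_high, size=(n, kk))
    offsets = np.cumsum(spacings, axis=1)
    offsets = offsets - offsets.mean(axis=1, keepdims=True)
    b = centers[:, None] + offsets

    ids = np.arange(1, n + 1)
    items = [
        ItemParameters(int(i), float(ai), tuple(bi))
        for i, ai, bi in zip(ids, a, b)
    ]
    short_ids = np.sort(ids[np.argsort(a)[::-1][: spec.short_size]])
    reverse_ids = (
        np.sort(rng.choice(ids, size=spec.reverse_size, replace=False))
        if spec.reverse_size
        else np.array([], dtype=int)
    )

    group_items = None
    group_offsets: dict[str, list] = {}
    if spec.groups:
        group_items = {}
        for grp in spec.groups:
            shift = (
                spec.dif_sd * rng.standard_normal(n) if spec.dif_sd > 0 else np.zeros(n)
            )
            group_offsets[grp] = shift.tolist()
            group_items[grp] = [
                ItemParameters(int(i), float(ai), tuple(bi + s), group=grp)
                for i, ai, bi, s in zip(ids, a, b, shift)
            ]

    bank = ItemBank(
        items,
        short_mask=[int(i) for i in short_ids],
        reverse_mask=[int(i) for i in reverse_ids],
        group_items=group_items,
    )
    truth = {
        "spec": asdict(spec),
        "seed": seed,
        "items": [
            {"id": int(i), "a": float(ai), "b": [float(x) for x in bi]}
            for i, ai, bi in zip(ids, a, b)
        ],
        "group_threshold_offsets": group_offsets,
    }
    return bank, truth


def _block_randomize(n: int, arms: tuple[str, ...], rng: np.random.Generator) -> list:
    """Permuted-block assignment: every consecutive block of len(arms)
    enrollees contains each arm exactly once."""
    out = []
    while len(out) < n:
        out.extend(rng.permutation(arms).tolist())
    return out[:n]


def generate_respondents(
    design: StudyDesign | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Roster of (respondent_id, site, sex, diagnosis, form, theta_true, arm)."""
    design = design or StudyDesign()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    frames = []
    for site, n, p_asd, p_male, p_pre, base in (
        ("clinical", design.n_clinical, design.p_asd_clinical,
         design.p_male_clinical, design.p_preschool_clinical,
         design.theta_baseline_clinical),
        ("general", design.n_general, design.p_asd_general,
         design.p_male_general, design.p_preschool_general,
         design.theta_baseline_general),
    ):
        if n == 0:
            continue
        asd = rng.random(n) < p_asd
        male = rng.random(n) < p_male
        pre = rng.random(n) < p_pre
        theta = (
            base
            + design.male_shift * male
            + design.case_shift * asd
            + design.theta_sd * rng.standard_normal(n)
        )
        if design.two_arm_first_n > 0:
            k = min(design.two_arm_first_n, n)
            arm = _block_randomize(k, ("full", "short"), rng)
            arm += _block_randomize(n - k, design.arms, rng)
        else:
            arm = _block_randomize(n, design.arms, rng)
        prefix = site[0].upper()
        frames.append(
            pd.DataFrame(
                {
                    "respondent_id": [f"{prefix}{i + 1:04d}" for i in range(n)],
                    "site": site,
                    "sex": np.where(male, "male", "female"),
                    "diagnosis": np.where(asd, "ASD", "non-ASD"),
                    "form": np.where(pre, "preschool", "school"),
                    "theta_true": theta,
                    "arm": arm,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _sample_matrix(
    bank: ItemBank, thetas: np.ndarray, groups, rng: np.random.Generator
) -> np.ndarray:
    """Keyed GRM response matrix (n_respondents, n_items) at the true thetas."""
    n = len(thetas)
    out = np.empty((n, bank.n_items), dtype=int)
    for r, (theta, grp) in enumerate(zip(thetas, groups)):
        u = rng.random(bank.n_items)
        for c, item_id in enumerate(bank.item_ids):
            star = _cumulative(bank.item(item_id, grp), float(theta))
            out[r, c] = int(np.sum(u[c] < star))
    return out


def generate_responses(
    roster: pd.DataFrame,
    bank: ItemBank,
    seed: int | None = None,
    remaining_items_protocol: bool = True,
    cat_config: CATConfig | None = None,
) -> pd.DataFrame:
    """Response table for the roster under the per-arm administration protocol.

    Every respondent receives a complete latent 65-item keyed response vector;
    the protocol decides which cells are recorded: full arm -> all items;
    short arm -> the 16 short items; cat arm -> the engine-administered items
    (driven by the same latent vector).  Under the remaining-items protocol
    (general site only) the shortened arms record all 65 items.  Stored
    responses are in raw orientation: reverse-coded items are un-keyed.
    """
    cat_config = cat_config or CATConfig()
    rng = np.random.default_rng(seed)
    kmax = bank.n_categories - 1
    groups = [
        group_label(f, s) if bank.groups else None
        for f, s in zip(roster["form"], roster["sex"])
    ]
    keyed = _sample_matrix(bank, roster["theta_true"].to_numpy(), groups, rng)
    raw = keyed.copy()
    for c, item_id in enumerate(bank.item_ids):
        if item_id in bank.reverse_mask:
            raw[:, c] = kmax - raw[:, c]

    id_to_col = {item_id: c for c, item_id in enumerate(bank.item_ids)}
    short_cols = [id_to_col[i] for i in bank.short_mask]

    records = np.full(raw.shape, np.nan)
    for r, (arm, site) in enumerate(zip(roster["arm"], roster["site"])):
        paired = remaining_items_protocol and site == "general"
        if arm == "full" or (paired and arm in ("short", "cat")):
            records[r, :] = raw[r, :]
        elif arm == "short":
            records[r, short_cols] = raw[r, short_cols]
        elif arm == "cat":
            provider = (lambda row: (lambda item_id: int(row[id_to_col[item_id]])))(
                raw[r]
            )
            result = administer(provider, bank, groups[r], cat_config)
            for item_id in result.state.administered:
                records[r, id_to_col[item_id]] = raw[r, id_to_col[item_id]]
        else:
            raise SrsCatError(f"unknown arm {arm!r}")

    out = roster.drop(columns=["theta_true"]).copy()
    for c, item_id in enumerate(bank.item_ids):
        out[f"item_{item_id}"] = records[:, c]
    return out


@dataclass
class SimulatedStudy:
    bank: ItemBank
    truth: dict
    roster: pd.DataFrame
    responses: pd.DataFrame
    design: StudyDesign
    bank_spec: SyntheticBankSpec
    seed: int | None = None


def simulate_study(
    design: StudyDesign | None = None,
    bank_spec: SyntheticBankSpec | None = None,
    seed: int | None = None,
    cat_config: CATConfig | None = None,
) -> SimulatedStudy:
    """Full synthetic study: bank, roster and protocol-driven responses, all
    derived from one seed."""
    design = design or StudyDesign()
    bank_spec = bank_spec or SyntheticBankSpec()
    ss = np.random.SeedSequence(seed)
    s_bank, s_roster, s_resp = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    bank, truth = generate_bank(bank_spec, s_bank)
    roster = generate_respondents(design, s_roster)
    responses = generate_responses(
        roster,
        bank,
        s_resp,
        remaining_items_protocol=design.remaining_items_protocol,
        cat_config=cat_config,
    )
    return SimulatedStudy(bank, truth, roster, responses, design, bank_spec, seed)


FIXTURE_PRESETS: Mapping[str, tuple[StudyDesign, int]] = {
    "tiny": (StudyDesign(n_clinical=14, n_general=16), 20220),
    "paper-scale": (StudyDesign(), 20221),
}


def make_fixture(name: str, out_dir=None, seed: int | None = None) -> SimulatedStudy:
    """Deterministic preset datasets ('tiny': n=30; 'paper-scale': n=355).

    Optionally writes bank.json, truth.json, roster.csv, responses.csv to
    ``out_dir``.  Regenerating with the recorded seed is byte-identical.
    """
    if name not in FIXTURE_PRESETS:
        raise SrsCatError(
            f"unknown preset {name!r}; available: {sorted(FIXTURE_PRESETS)}"
        )
    design, preset_seed = FIXTURE_PRESETS[name]
    study = simulate_study(design, seed=preset_seed if seed is None else seed)
    if out_dir is not None:
        from . import io as _io  # deferred to avoid a cycle

        _io.write_study(study, out_dir)
    return study
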