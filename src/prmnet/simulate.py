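"""Synthetic study generator for the targeted insoluble-proteome workflow.

Emulates a 44-case postmortem cohort (12 CTL / 8 AsymAD / 12 AD / 12 PD)
measured by parallel reaction monitoring: an 870-peptide target list
rolling up to 390 entities (385 RNA-binding proteins plus MAPT, APP, an
amyloid-beta region entity and two spare slots), transition-level peak
areas with multiplicative injection-order signal drift, a 6-peptide x
5-level tenfold-dilution heavy reference spike-in, planted co-abundance
modules with disease-specific insolubility shifts, lognormal measurement
noise, and rare missing values.

Ground truth (module membership, planted effects, noise-free abundances)
is returned alongside the data so every downstream stage can be tested
against what was planted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .quant import compute_precursor_mz

GROUPS = ("CTL", "AsymAD", "AD", "PD")

#: Cohort summary statistics used as generator parameters
#: (per-group mean, SD; male fraction; score means/SDs).
COHORT_STATS = {
    "CTL": dict(n=12, age=(76.0, 10.5), pmi=(7.3, 3.9), male=0.500,
                cerad=(0.2, 0.4), braak=(1.6, 0.9), abc=(0.5, 0.5)),
    "AsymAD": dict(n=8, age=(82.5, 9.7), pmi=(17.5, 9.6), male=0.625,
                   cerad=(2.8, 0.5), braak=(3.0, 1.2), abc=(1.8, 0.5)),
    "AD": dict(n=12, age=(76.4, 7.4), pmi=(9.5, 8.2), male=0.667,
               cerad=(3.0, 0.0), braak=(5.9, 0.3), abc=(3.0, 0.0)),
    "PD": dict(n=12, age=(75.1, 6.0), pmi=(12.9, 7.6), male=0.750,
               cerad=(0.2, 0.4), braak=(2.2, 1.3), abc=(0.4, 0.5)),
}
DLB_NEOCORTEX_RATE = 0.5  # PD only, binary

_AA = "ACDEFGHILMNPQSTVWY"  # standard residues minus K/R (appended as terminus)


@dataclass(frozen=True)
class ReferenceMixDesign:
    """The 6 x 5 isotopologue spike-in: 6 peptide sets, 5 dilution levels.

    Levels form an exact tenfold geometric series from 0.0001x to 1x and
    the same nominal amount is spiked into every injection.
    """

    n_peptide_sets: int = 6
    n_levels: int = 5
    spike_amount: float = 1.0e6  # peak-area units of the 1x isotopologue

    @property
    def level_ratios(self) -> tuple:
        return tuple(10.0 ** (k - self.n_levels + 1) for k in range(self.n_levels))

    def validate(self) -> None:
        ratios = self.level_ratios
        for a, b in zip(ratios, ratios[1:]):
            if not np.isclose(b / a, 10.0):
                raise ConfigurationError("reference levels must be a tenfold series")


def _default_effects() -> tuple:
    # planted disease shifts, log2 units, keyed by planted module index:
    # module 1: snRNP-like, tau/Abeta-tracking, stage-specific AsymAD/AD gain;
    # module 2: AD-only gain; module 3: AD loss (FET-like);
    # module 4: PD loss (translation-like).
    return (
        (1, "AsymAD", 0.8),
        (1, "AD", 1.2),
        (2, "AD", 0.8),
        (3, "AD", -0.8),
        (4, "PD", -0.8),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study.

    Defaults reproduce the study conditions: group sizes 12/8/12/12,
    390 entities from 870 peptides, 29 planted modules of 5-60 members
    at within-module correlation 0.7, drift line 1.417 - 0.0167*j over
    50 injections, and 0.73% missing protein values.
    """

    group_sizes: tuple = ((("CTL", 12), ("AsymAD", 8), ("AD", 12), ("PD", 12)))
    n_proteins: int = 390
    n_peptides: int = 870
    n_modules_planted: int = 29
    module_size_range: tuple = (5, 60)
    within_module_cor: float = 0.7
    biological_sd: float = 0.6      # log2 units of biological variation
    effect_table: tuple = field(default_factory=_default_effects)
    drift_slope: float = -0.0167    # ratio units per injection
    drift_intercept: float = 1.417
    noise_cv: float = 0.15          # lognormal measurement noise, CV fraction
    missing_rate: float = 0.0073
    age_slope: float = 0.01         # log2 units per year
    sex_effect: float = 0.10        # log2 units, F vs M
    pmi_slope: float = 0.01         # log2 units per hour
    n_pooled_injections: int = 6
    mapt_peptides: int = 35
    app_peptides: int = 9
    abeta_peptides: int = 3         # of the APP peptides, these map to 597-638
    extra_entities: tuple = ("IS1", "IS2")
    reference: ReferenceMixDesign = field(default_factory=ReferenceMixDesign)
    seed: int = 17

    # -- derived --------------------------------------------------------
    @property
    def n_cases(self) -> int:
        return sum(n for _, n in self.group_sizes)

    @property
    def n_injections(self) -> int:
        return self.n_cases + self.n_pooled_injections

    def validate(self) -> None:
        for g, n in self.group_sizes:
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group {g!r}")
            if n < 0:
                raise ConfigurationError(f"negative group size for {g}")
        if self.n_cases < 1:
            raise ConfigurationError("at least one case required")
        if self.n_peptides < self.n_proteins:
            raise ConfigurationError("need at least one peptide per protein")
        lo, hi = self.module_size_range
        if lo < 2 or hi < lo:
            raise ConfigurationError(f"bad module_size_range {self.module_size_range}")
        if not 0 <= self.within_module_cor <= 1:
            raise ConfigurationError("within_module_cor must be in [0,1]")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0,1)")
        if self.n_modules_planted * lo > self.n_proteins:
            raise ConfigurationError("planted modules cannot exceed n_proteins")
        if self.abeta_peptides >= self.app_peptides:
            raise ConfigurationError("abeta_peptides must be < app_peptides")
        self.reference.validate()

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream keyed off the config seed."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


# deterministic RNG stream ids
_S_COHORT, _S_TARGETS, _S_MODULES, _S_LATENT, _S_PNOISE = 0, 1, 2, 3, 4
_S_SHARES, _S_MISSING, _S_TNOISE, _S_REFNOISE = 5, 6, 7, 8


# ---------------------------------------------------------------------------
# cohort

def pooled_injection_positions(config: SimulationConfig) -> list[int]:
    """Evenly spaced 1-based injection positions of the pooled standards."""
    n = config.n_injections
    k = config.n_pooled_injections
    if k == 0:
        return []
    pos = np.linspace(1, n, k + 2)[1:-1]
    out, used = [], set()
    for p in pos:
        q = int(round(p))
        while q in used:
            q += 1
        used.add(q)
        out.append(q)
    return out


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate the case-metadata table.

    Ages and PMIs are drawn from per-group normal distributions (means
    and SDs of the cohort summary table), truncated at zero; sexes follow
    the per-group male fractions; CERAD/Braak/ABC scores are clipped,
    rounded normal draws around the group means. Case injection indices
    are a random permutation of the non-pooled positions.
    """
    config.validate()
    rng = config.rng(_S_COHORT)
    pooled = set(pooled_injection_positions(config))
    case_positions = [j for j in range(1, config.n_injections + 1) if j not in pooled]
    case_positions = list(rng.permutation(case_positions))

    def trunc_normal(mean, sd, lo=0.0, hi=np.inf):
        while True:
            x = rng.normal(mean, sd)
            if lo <= x <= hi:
                return x

    rows = []
    i = 0
    for group, n in config.group_sizes:
        st = COHORT_STATS[group]
        for _ in range(n):
            i += 1
            sex = "M" if rng.random() < st["male"] else "F"
            row = {
                "case_id": f"{group}_{i:02d}",
                "group": group,
                "age_death": round(trunc_normal(*st["age"]), 1),
                "sex": sex,
                "pmi": round(trunc_normal(*st["pmi"]), 1),
                "cerad": int(np.clip(round(rng.normal(*st["cerad"])), 0, 3)),
                "braak": int(np.clip(round(rng.normal(*st["braak"])), 0, 6)),
                "abc": int(np.clip(round(rng.normal(*st["abc"])), 0, 3)),
                "dlb_neocortex": (
                    int(rng.random() < DLB_NEOCORTEX_RATE) if group == "PD" else np.nan
                ),
                "injection_index": int(case_positions[i - 1]),
            }
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# target list

def _random_peptide(rng: np.random.Generator, existing: set) -> str:
    while True:
        length = int(rng.integers(7, 20))
        body = "".join(rng.choice(list(_AA), size=length - 1))
        pep = body + ("K" if rng.random() < 0.5 else "R")
        if pep not in existing:
            existing.add(pep)
            return pep


def entity_names(config: SimulationConfig) -> list[str]:
    """Roll-up entity names: RBPs, MAPT, APP, Abeta and the extra slots."""
    n_rbp = config.n_proteins - 3 - len(config.extra_entities)
    if n_rbp < 1:
        raise ConfigurationError("n_proteins too small for the fixed entities")
    rbps = [f"RBP{i:03d}" for i in range(1, n_rbp + 1)]
    return rbps + ["MAPT", "APP", "Abeta"] + list(config.extra_entities)


def generate_target_list(config: SimulationConfig) -> pd.DataFrame:
    """Build the peptide inclusion list.

    MAPT receives 35 peptides and APP 9, of which the amyloid-beta-region
    peptides are flagged with roll-up entity ``Abeta``; remaining peptides
    are spread over the RBP entities (every entity gets at least one).
    Reference spike-in rows (6 sets x 5 levels) are appended with
    ``is_reference=True``.
    """
    config.validate()
    rng = config.rng(_S_TARGETS)
    names = entity_names(config)
    rbps = [n for n in names if n.startswith("RBP")]
    extras = list(config.extra_entities)

    budget = config.n_peptides - config.mapt_peptides - config.app_peptides - len(extras)
    if budget < len(rbps):
        raise ConfigurationError("n_peptides too small for one peptide per RBP")
    base = budget // len(rbps)
    remainder = budget - base * len(rbps)
    counts = {r: base + (1 if k < remainder else 0) for k, r in enumerate(rbps)}

    existing: set = set()
    rows = []

    def add(protein, entity, n):
        for _ in range(n):
            pep = _random_peptide(rng, existing)
            charge = int(rng.integers(2, 4))
            rows.append(
                dict(protein=protein, entity=entity, peptide=pep, charge=charge,
                     precursor_mz=round(compute_precursor_mz(pep, charge), 4),
                     is_reference=False, reference_level=0)
            )

    for r in rbps:
        add(r, r, counts[r])
    add("MAPT", "MAPT", config.mapt_peptides)
    add("APP", "Abeta", config.abeta_peptides)   # residues 597-638 of APP_695
    add("APP", "APP", config.app_peptides - config.abeta_peptides)
    for e in extras:
        add(e, e, 1)

    design = config.reference
    for s in range(1, design.n_peptide_sets + 1):
        seq = _random_peptide(rng, existing)
        for level in range(1, design.n_levels + 1):
            rows.append(
                dict(protein="REFMIX", entity="REFMIX",
                     peptide=f"{seq}(heavy{level})", charge=2,
                     precursor_mz=round(compute_precursor_mz(seq, 2), 4),
                     is_reference=True, reference_level=level)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# planted truth

def planted_module_sizes(config: SimulationConfig) -> list[int]:
    """Deterministic module sizes: a rank-power-law decay clipped to range.

    Sizes follow round(hi * rank^-0.8) clipped to [lo, hi]; if the total
    would exceed n_proteins the largest modules are shrunk.
    """
    lo, hi = config.module_size_range
    sizes = [max(lo, min(hi, round(hi * (r + 1) ** -0.8)))
             for r in range(config.n_modules_planted)]
    while sum(sizes) > config.n_proteins:
        k = int(np.argmax(sizes))
        if sizes[k] <= lo:
            raise ConfigurationError("planted modules cannot fit into n_proteins")
        sizes[k] -= 1
    return sizes


def planted_assignment(config: SimulationConfig) -> dict:
    """entity -> planted module index (0 = background).

    MAPT and Abeta are planted inside module 1 (the pathology-tracking
    module); APP and the extra slots stay background.
    """
    names = entity_names(config)
    sizes = planted_module_sizes(config)
    assign = {n: 0 for n in names}
    pool = [n for n in names if n.startswith("RBP")]
    pos = 0
    for m, size in enumerate(sizes, start=1):
        take = size
        if m == 1:
            for anchor in ("MAPT", "Abeta"):
                assign[anchor] = 1
                take -= 1
        for n in pool[pos : pos + take]:
            assign[n] = m
        pos += take
    return assign


def _group_shift(config: SimulationConfig) -> dict:
    shift = {}
    for module, group, delta in config.effect_table:
        shift[(int(module), group)] = shift.get((int(module), group), 0.0) + float(delta)
    return shift


def true_log2_matrix(cohort: pd.DataFrame, config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Noise-free planted log2 abundances (entities x cases) plus truth.

    Model per entity p in module m and sample s:
    ``base_p + sd * (sqrt(c) f_m(s) + sqrt(1-c) e_p(s)) + shift(m, group_s)
    + covariate terms`` where c is the within-module correlation and f_m
    are iid standard-normal module factors.
    """
    config.validate()
    names = entity_names(config)
    assign = planted_assignment(config)
    rng_base = config.rng(_S_MODULES)
    rng_lat = config.rng(_S_LATENT)
    n_s = len(cohort)
    base = rng_base.normal(17.0, 1.5, size=len(names))
    factors = rng_lat.standard_normal((config.n_modules_planted + 1, n_s))
    eps = rng_lat.standard_normal((len(names), n_s))
    c = config.within_module_cor
    shift = _group_shift(config)

    age = cohort["age_death"].to_numpy(float)
    sex = cohort["sex"].map({"M": 0.0, "F": 1.0}).to_numpy(float)
    pmi = cohort["pmi"].to_numpy(float)
    cov = (
        config.age_slope * (age - age.mean())
        + config.sex_effect * (sex - sex.mean())
        + config.pmi_slope * (pmi - pmi.mean())
    )
    groups = cohort["group"].to_numpy()

    mat = np.empty((len(names), n_s))
    for i, name in enumerate(names):
        m = assign[name]
        if m > 0:
            z = np.sqrt(c) * factors[m] + np.sqrt(1.0 - c) * eps[i]
        else:
            z = eps[i]
        row = base[i] + config.biological_sd * z + cov
        if m > 0:
            row = row + np.array([shift.get((m, g), 0.0) for g in groups])
        mat[i] = row
    df = pd.DataFrame(mat, index=names, columns=list(cohort["case_id"]))
    truth = {
        "assignment": assign,
        "module_sizes": planted_module_sizes(config),
        "effect_table": [list(e) for e in config.effect_table],
        "base_log2": dict(zip(names, base.tolist())),
    }
    return df, truth


def _lognormal_factor(rng, cv, shape):
    if cv <= 0:
        return np.ones(shape)
    s = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * s * s, s, size=shape))


def missingness_mask(cohort: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Entity x case boolean mask of missing (zeroed) quantities.

    Drawn once per entity x sample; when an entity is missing in a sample
    every peptide of that entity is zero in that injection, so the
    protein-level zero fraction equals ``missing_rate`` in expectation.
    """
    rng = config.rng(_S_MISSING)
    names = entity_names(config)
    mask = rng.random((len(names), len(cohort))) < config.missing_rate
    return pd.DataFrame(mask, index=names, columns=list(cohort["case_id"]))


def generate_protein_matrix(
    cohort: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, dict]:
    """Linear-scale protein x case abundance matrix with noise and zeros.

    Shortcut around the transition layer (no drift, which the correction
    cancels anyway): observed = 2**true_log2 * lognormal(noise_cv), with
    entity x sample missingness zeros applied. Returns (matrix, truth).
    """
    true_log2, truth = true_log2_matrix(cohort, config)
    rng = config.rng(_S_PNOISE)
    linear = np.power(2.0, true_log2.to_numpy())
    linear = linear * _lognormal_factor(rng, config.noise_cv, linear.shape)
    mask = missingness_mask(cohort, config)
    linear = np.where(mask.to_numpy(), 0.0, linear)
    df = pd.DataFrame(linear, index=true_log2.index, columns=true_log2.columns)
    truth = dict(truth)
    truth["true_log2"] = true_log2
    truth["missing_mask"] = mask
    return df, truth


# ---------------------------------------------------------------------------
# transitions

def drift_multiplier(config: SimulationConfig, injections: np.ndarray) -> np.ndarray:
    """Per-injection multiplicative drift: intercept + slope * j (1-based)."""
    d = config.drift_intercept + config.drift_slope * np.asarray(injections, float)
    if (d <= 0).any():
        raise ConfigurationError("drift line reaches zero within the run; "
                                 "shorten the run or flatten the slope")
    return d


def generate_transitions(
    cohort: pd.DataFrame,
    targets: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate the transition-level peak-area table and reference areas.

    Every injection (cases plus pooled standards) yields 3-6 product-ion
    rows per peptide. Observed area = true peptide amount x fragment
    share x drift(injection) x lognormal noise; the reference spike-ins
    follow the 6 x 5 tenfold design times the same drift. Entities flagged
    missing for a case have all of their transitions zeroed there.

    Returns ``(transition_table, reference_areas, truth)`` where
    ``reference_areas`` is a (reference peptide x injection) area grid.
    """
    config.validate()
    true_log2, truth = true_log2_matrix(cohort, config)
    mask = missingness_mask(cohort, config)
    rng_sh = config.rng(_S_SHARES)
    rng_tn = config.rng(_S_TNOISE)
    rng_rn = config.rng(_S_REFNOISE)

    sample_by_inj = dict(zip(cohort["injection_index"], cohort["case_id"]))
    gps_positions = pooled_injection_positions(config)
    for k, j in enumerate(gps_positions, start=1):
        sample_by_inj[j] = f"GPS{k}"
    injections = sorted(sample_by_inj)
    drift = dict(zip(injections, drift_multiplier(config, np.array(injections))))

    linear_true = np.power(2.0, true_log2)
    pooled_profile = linear_true.mean(axis=1)

    endo = targets.loc[~targets["is_reference"]].reset_index(drop=True)
    n_pep = len(endo)
    # fixed per-peptide ionization share within its entity, and 3-6 fragments
    share_raw = rng_sh.gamma(2.0, size=n_pep)
    share = pd.Series(share_raw, index=endo.index)
    share = share / share.groupby(endo["entity"].to_numpy()).transform("sum")
    n_frag = rng_sh.integers(3, 7, size=n_pep)
    frag_share = [rng_sh.dirichlet(np.full(k, 2.0)) for k in n_frag]
    frag_labels = [[f"y{3 + f}" for f in range(k)] for k in n_frag]

    records = []
    case_cols = list(cohort["case_id"])
    for j in injections:
        sid = sample_by_inj[j]
        if sid.startswith("GPS"):
            prof = pooled_profile
            miss = None
        else:
            prof = linear_true[sid]
            miss = mask[sid]
        d = drift[j]
        pep_noise = _lognormal_factor(rng_tn, config.noise_cv, n_pep)
        for i in range(n_pep):
            ent = endo.at[i, "entity"]
            amount = prof[ent] * share.iloc[i]
            if miss is not None and miss[ent]:
                amount = 0.0
            q = amount * d * pep_noise[i]
            for lab, fs in zip(frag_labels[i], frag_share[i]):
                records.append(
                    (j, sid, endo.at[i, "protein"], ent, endo.at[i, "peptide"],
                     int(endo.at[i, "charge"]), lab, q * fs)
                )

    # reference spike-ins: same nominal amount in every injection
    design = config.reference
    ref = targets.loc[targets["is_reference"]].reset_index(drop=True)
    ratios = design.level_ratios
    ref_frag_share = [rng_sh.dirichlet(np.full(3, 2.0)) for _ in range(len(ref))]
    ref_rows = {p: [] for p in ref["peptide"]}
    for j in injections:
        sid = sample_by_inj[j]
        d = drift[j]
        noise = _lognormal_factor(rng_rn, config.noise_cv, len(ref))
        for i in range(len(ref)):
            level = int(ref.at[i, "reference_level"])
            q = design.spike_amount * ratios[level - 1] * d * noise[i]
            ref_rows[ref.at[i, "peptide"]].append(q)
            for lab, fs in zip(("y3", "y4", "y5"), ref_frag_share[i]):
                records.append(
                    (j, sid, "REFMIX", "REFMIX", ref.at[i, "peptide"],
                     int(ref.at[i, "charge"]), lab, q * fs)
                )

    table = pd.DataFrame(
        records,
        columns=["injection_index", "sample_id", "protein", "entity",
                 "peptide", "charge", "fragment_ion", "area"],
    )
    reference_areas = pd.DataFrame(ref_rows, index=injections).T
    reference_areas.index.name = "peptide"
    truth = dict(truth)
    truth["true_log2"] = true_log2
    truth["missing_mask"] = mask
    truth["gps_injections"] = gps_positions
    truth["drift"] = drift
    return table, reference_areas, truth


def generate_annotation_sets(
    config: SimulationConfig,
    n_noise_terms: int = 10,
    frac_extra: float = 0.2,
) -> dict:
    """Synthetic gene-set annotations aligned with the planted modules.

    One term per planted module (the module's members plus a fraction of
    random background entities, emulating imperfect ontology curation)
    plus random noise terms, suitable as input to the enrichment stage.
    """
    rng = config.rng(9)
    names = entity_names(config)
    assign = planted_assignment(config)
    sets = {}
    for m in range(1, config.n_modules_planted + 1):
        members = [n for n, mm in assign.items() if mm == m]
        n_extra = int(round(frac_extra * len(members)))
        extras = list(rng.choice(names, size=n_extra, replace=False))
        sets[f"TERM_M{m:02d}"] = sorted(set(members) | set(extras))
    for t in range(1, n_noise_terms + 1):
        size = int(rng.integers(5, min(40, len(names) + 1)))
        sets[f"TERM_RND{t:02d}"] = sorted(rng.choice(names, size=size, replace=False))
    return sets


# ---------------------------------------------------------------------------
# serialization helpers

def write_truth_json(truth: dict, path) -> None:
    """Persist the ground truth (module labels, effects) for test oracles."""
    out = {
        "assignment": truth["assignment"],
        "module_sizes": truth["module_sizes"],
        "effect_table": truth["effect_table"],
    }
    if "gps_injections" in truth:
        out["gps_injections"] = list(truth["gps_injections"])
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from a plain (e.g. YAML-loaded) mapping."""
    d = dict(d)
    if "group_sizes" in d:
        d["group_sizes"] = tuple((g, int(n)) for g, n in d["group_sizes"])
    if "effect_table" in d:
        d["effect_table"] = tuple(tuple(e) for e in d["effect_table"])
    if "reference" in d and isinstance(d["reference"], dict):
        d["reference"] = ReferenceMixDesign(**d["reference"])
    if "module_size_range" in d:
        d["module_size_range"] = tuple(d["module_size_range"])
    if "extra_entities" in d:
        d["extra_entities"] = tuple(d["extra_entities"])
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown simulation options: {sorted(unknown)}")
    return SimulationConfig(**d)
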