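"""Seeded generators of complete synthetic deletion-library screens.

A chemical-genomic screen spots ~4850 single-gene deletion strains of
*S. cerevisiae* on drug-containing agar at several concentrations, with a
wild-type and a known-sensitive (spt3Δ) control well on every 96-well
plate.  The generators here emulate that design end to end — spotted
growth, liquid-culture OD600 endpoints, DNA-content/PI cytometry events
and budding counts — with a known ground-truth class per strain, so every
downstream stage of the pipeline can be tested without any real data.

Dose response is modelled as Hill-type growth inhibition

    g(c) = g0 / (1 + (c / IC50)^h)

with a strain-class-specific IC50 and multiplicative lognormal spot noise
of a given coefficient of variation.  Sensitive strains carry a low IC50,
resistant strains a high one, unaffected strains the wild-type value.
"""

from __future__ import annotations

import dataclasses
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WT_STRAIN = "BY4741"
SENS_CONTROL_STRAIN = "spt3"

PLATE_ROWS = list(string.ascii_uppercase[:8])
PLATE_COLS = list(range(1, 13))

CLASS_SENSITIVE = "sensitive"
CLASS_RESISTANT = "resistant"
CLASS_UNAFFECTED = "unaffected"


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic screen.

    Defaults mirror the study design of the real screen: 4852 library
    strains, three drug concentrations (55, 67.5 and 72.5 µM) and two
    biological replicates.

    Parameters
    ----------
    n_strains : number of library strains (controls are extra).
    frac_sensitive, frac_resistant : class proportions; remainder is
        unaffected.
    concentrations : treated drug concentrations in µM (untreated 0 µM
        spots are always emitted as well).
    n_replicates : biological replicates of the whole screen.
    noise_cv : coefficient of variation of the multiplicative lognormal
        noise applied per spot / per OD reading.
    ic50_sensitive, ic50_wildtype, ic50_resistant : Hill IC50 scale (µM)
        for each true class; unaffected strains use the wild-type value.
    hill : Hill steepness of the inhibition curve.
    seed : RNG seed; identical configs give byte-identical outputs.
    """

    n_strains: int = 4852
    frac_sensitive: float = 0.084  # ~407/4852 in the real screen
    frac_resistant: float = 0.016  # ~80/4852
    concentrations: tuple[float, ...] = (55.0, 67.5, 72.5)
    n_replicates: int = 2
    noise_cv: float = 0.1
    ic50_sensitive: float = 45.0
    ic50_wildtype: float = 78.0
    ic50_resistant: float = 200.0
    hill: float = 6.0
    baseline_growth: float = 1.0
    baseline_cv: float = 0.15  # strain-to-strain spread of untreated growth
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_sensitive <= 1.0 and 0.0 <= self.frac_resistant <= 1.0):
            raise ConfigurationError("class fractions must lie in [0, 1]")
        if self.frac_sensitive + self.frac_resistant > 1.0:
            raise ConfigurationError("frac_sensitive + frac_resistant must be <= 1")
        if len(self.concentrations) == 0 or any(c <= 0 for c in self.concentrations):
            raise ConfigurationError("all treated concentrations must be > 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if self.n_strains < 1:
            raise ConfigurationError("n_strains must be >= 1")
        if min(self.ic50_sensitive, self.ic50_wildtype, self.ic50_resistant) <= 0:
            raise ConfigurationError("IC50 parameters must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["concentrations"] = list(self.concentrations)
        return d


@dataclass
class PlateLayout:
    """An 8x12 plate map: well address -> strain id, plus control wells."""

    plate_id: str
    wells: dict[str, str] = field(default_factory=dict)
    control_wells: dict[str, str] = field(default_factory=dict)  # well -> control tag

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "plate_id": self.plate_id,
                "well": w,
                "strain_id": s,
                "control": self.control_wells.get(w, ""),
            }
            for w, s in sorted(self.wells.items())
        ]
        return pd.DataFrame(rows)


def _lognormal_sigma(cv: float) -> float:
    # sigma of ln X for a lognormal with E[X]=1 and the given CV
    return float(np.sqrt(np.log(1.0 + cv * cv)))


def _noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise."""
    if cv == 0:
        return np.ones(size)
    sig = _lognormal_sigma(cv)
    return rng.lognormal(mean=-0.5 * sig * sig, sigma=sig, size=size)


def hill_growth(baseline: float, conc: float, ic50: float, hill: float) -> float:
    """Noise-free growth under Hill-type inhibition; conc=0 gives baseline."""
    if conc == 0:
        return baseline
    return baseline / (1.0 + (conc / ic50) ** hill)


def _assign_classes(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_sens = int(round(cfg.n_strains * cfg.frac_sensitive))
    n_res = int(round(cfg.n_strains * cfg.frac_resistant))
    classes = np.array(
        [CLASS_SENSITIVE] * n_sens
        + [CLASS_RESISTANT] * n_res
        + [CLASS_UNAFFECTED] * (cfg.n_strains - n_sens - n_res)
    )
    rng.shuffle(classes)
    ic50_map = {
        CLASS_SENSITIVE: cfg.ic50_sensitive,
        CLASS_RESISTANT: cfg.ic50_resistant,
        CLASS_UNAFFECTED: cfg.ic50_wildtype,
    }
    return pd.DataFrame(
        {
            "strain_id": [f"STR{i:04d}" for i in range(1, cfg.n_strains + 1)],
            "true_class": classes,
            "true_ic50": [ic50_map[c] for c in classes],
        }
    )


def build_plate_layouts(strain_ids: list[str]) -> list[PlateLayout]:
    """Array strains onto 96-well plates, 94 library wells per plate.

    A1 carries the wild-type control and H12 the sensitive spt3Δ control
    on every plate.
    """
    layouts: list[PlateLayout] = []
    addresses = [f"{r}{c}" for r in PLATE_ROWS for c in PLATE_COLS]
    library_addresses = [a for a in addresses if a not in ("A1", "H12")]
    per_plate = len(library_addresses)
    n_plates = int(np.ceil(len(strain_ids) / per_plate))
    for p in range(n_plates):
        plate_id = f"P{p + 1:02d}"
        chunk = strain_ids[p * per_plate : (p + 1) * per_plate]
        wells = {"A1": WT_STRAIN, "H12": SENS_CONTROL_STRAIN}
        wells.update(dict(zip(library_addresses, chunk)))
        layouts.append(
            PlateLayout(
                plate_id=plate_id,
                wells=wells,
                control_wells={"A1": "wild_type", "H12": "sensitive_control"},
            )
        )
    return layouts


def simulate_screen(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[PlateLayout]]:
    """Simulate a full spotted agar screen.

    Returns
    -------
    growth : long-format table (strain_id, plate_id, well, concentration,
        replicate, growth) including untreated (0 µM) spots and the
        control wells of every plate.
    truth : GroundTruth table (strain_id, true_class, true_ic50) for the
        library strains.
    layouts : list of PlateLayout, one per 96-well plate.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = _assign_classes(cfg, rng)
    layouts = build_plate_layouts(list(truth["strain_id"]))

    ic50 = dict(zip(truth["strain_id"], truth["true_ic50"]))
    ic50[WT_STRAIN] = cfg.ic50_wildtype
    ic50[SENS_CONTROL_STRAIN] = cfg.ic50_sensitive

    # per-strain untreated baseline (strain-to-strain growth-rate spread)
    strains_all = list(ic50)
    baseline = dict(
        zip(
            strains_all,
            cfg.baseline_growth * _noise(rng, cfg.baseline_cv, len(strains_all)),
        )
    )

    conditions = [0.0] + [float(c) for c in cfg.concentrations]
    records = []
    for layout in layouts:
        for well, strain in sorted(layout.wells.items()):
            for rep in range(1, cfg.n_replicates + 1):
                for conc in conditions:
                    mu = hill_growth(baseline[strain], conc, ic50[strain], cfg.hill)
                    records.append((strain, layout.plate_id, well, conc, rep, mu))
    growth = pd.DataFrame(
        records,
        columns=["strain_id", "plate_id", "well", "concentration", "replicate", "growth"],
    )
    growth["growth"] = growth["growth"].to_numpy() * _noise(rng, cfg.noise_cv, len(growth))
    return growth, truth, layouts


def simulate_od600(
    cfg: SimConfig,
    strains: list[str] | pd.DataFrame,
    concentrations: tuple[float, ...] | None = None,
    n_replicates: int = 3,
    n_wt_replicates: int = 12,
    hours: float = 20.0,
    batch: str = "B1",
) -> pd.DataFrame:
    """Simulate endpoint OD600 of a liquid-culture validation experiment.

    Cultures follow logistic growth for `hours` hours with the growth rate
    scaled by the same Hill inhibition factor as the agar screen; the
    endpoint OD is read once per replicate.  Wild-type rows are always
    present in the batch so NTGV normalisation is possible; the wild-type
    reference gets a full plate column of replicate wells (default 12)
    because its noise propagates into every strain's NTGV.

    `strains` may be a list of strain ids (their true class is then looked
    up from a GroundTruth frame passed instead) or a GroundTruth DataFrame
    subset.
    """
    if isinstance(strains, pd.DataFrame):
        truth = strains
    else:
        raise LookupError(
            "simulate_od600 needs the GroundTruth rows of the strains "
            "(pass a DataFrame with strain_id/true_ic50 columns)"
        )
    missing = truth["true_ic50"].isna()
    if missing.any():
        raise LookupError(f"unknown strain ids: {list(truth.loc[missing, 'strain_id'])}")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 600]))
    if concentrations is None:
        concentrations = (50.0,)

    od0, carrying, rate0 = 0.005, 1.0, 0.5  # /h; untreated reaches stationary by 20 h
    ic50 = dict(zip(truth["strain_id"], truth["true_ic50"]))
    ic50[WT_STRAIN] = cfg.ic50_wildtype

    records = []
    for strain in [WT_STRAIN] + [s for s in ic50 if s != WT_STRAIN]:
        for conc in [0.0] + [float(c) for c in concentrations]:
            inhib = hill_growth(1.0, conc, ic50[strain], cfg.hill)
            rate = rate0 * inhib
            od = carrying / (1.0 + (carrying - od0) / od0 * np.exp(-rate * hours))
            reps = n_wt_replicates if strain == WT_STRAIN else n_replicates
            for rep in range(1, reps + 1):
                records.append((strain, conc, rep, od, batch))
    od_table = pd.DataFrame(
        records, columns=["strain_id", "condition", "replicate", "od600", "batch"]
    )
    od_table["od600"] = od_table["od600"].to_numpy() * _noise(rng, cfg.noise_cv, len(od_table))
    return od_table


@dataclass
class CytometrySample:
    """Per-event cytometry readout for one sample.

    dna_content is on an arbitrary 1C/2C fluorescence scale; pi_value is
    the propidium-iodide intensity per event.
    """

    sample_id: str
    dna_content: np.ndarray
    pi_value: np.ndarray
    treatment: str = ""
    timepoint: float = 0.0

    def __post_init__(self) -> None:
        self.dna_content = np.asarray(self.dna_content, dtype=float)
        self.pi_value = np.asarray(self.pi_value, dtype=float)
        if self.dna_content.size == 0 or self.pi_value.size == 0:
            raise ConfigurationError("event lists must be non-empty")
        if not (np.all(np.isfinite(self.dna_content)) and np.all(self.dna_content >= 0)):
            raise ConfigurationError("dna_content values must be finite and >= 0")
        if not (np.all(np.isfinite(self.pi_value)) and np.all(self.pi_value >= 0)):
            raise ConfigurationError("pi_value values must be finite and >= 0")


def simulate_cytometry(
    n_cells: int,
    g1_frac: float,
    pi_frac: float,
    seed: int,
    sample_id: str = "sim",
    c1_mean: float = 100.0,
    cv_peak: float = 0.08,
    s_phase_frac: float = 0.0,
    pi_pos_mean: float = 50.0,
    pi_neg_mean: float = 2.0,
    treatment: str = "",
    timepoint: float = 0.0,
) -> CytometrySample:
    """Draw a synthetic DNA-content / PI event sample.

    DNA content is a two-component normal mixture: a 1C peak at
    ``c1_mean`` with weight ``g1_frac`` and a 2C peak at twice that mean,
    each with coefficient of variation ``cv_peak``, plus an optional
    uniform S-phase bridge between the peaks with weight
    ``s_phase_frac``.  PI positivity is Bernoulli(``pi_frac``) with a
    well-separated positive intensity mode.
    """
    if not (0.0 <= g1_frac <= 1.0 and 0.0 <= pi_frac <= 1.0 and 0.0 <= s_phase_frac < 1.0):
        raise ConfigurationError("g1_frac, pi_frac and s_phase_frac must be probabilities")
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)

    c2_mean = 2.0 * c1_mean
    u = rng.random(n_cells)
    dna = np.empty(n_cells)
    in_s = u < s_phase_frac
    in_g1 = (~in_s) & (u < s_phase_frac + (1.0 - s_phase_frac) * g1_frac)
    in_g2 = ~(in_s | in_g1)
    dna[in_s] = rng.uniform(c1_mean, c2_mean, in_s.sum())
    dna[in_g1] = rng.normal(c1_mean, cv_peak * c1_mean, in_g1.sum())
    dna[in_g2] = rng.normal(c2_mean, cv_peak * c2_mean, in_g2.sum())
    dna = np.clip(dna, 0.0, None)

    pos = rng.random(n_cells) < pi_frac
    pi = np.where(
        pos,
        rng.lognormal(np.log(pi_pos_mean), 0.25, n_cells),
        rng.lognormal(np.log(pi_neg_mean), 0.5, n_cells),
    )
    return CytometrySample(
        sample_id=sample_id,
        dna_content=dna,
        pi_value=pi,
        treatment=treatment,
        timepoint=timepoint,
    )


def simulate_budding_counts(
    n_cells: int, budded_frac: float, seed: int
) -> tuple[int, int]:
    """Binomial budded/unbudded counts for a microscopy field."""
    if not 0.0 <= budded_frac <= 1.0:
        raise ConfigurationError("budded_frac must be a probability")
    rng = np.random.default_rng(seed)
    budded = int(rng.binomial(n_cells, budded_frac))
    return budded, n_cells - budded


def make_annotation_sets(
    truth: pd.DataFrame,
    n_random_terms: int = 50,
    term_size: int = 12,
    planted_term: str = "PLANTED:SAGA_like",
    planted_size: int = 12,
    planted_hit_frac: float = 0.9,
    seed: int = 0,
) -> dict[str, tuple[str, list[str]]]:
    """Build synthetic annotation sets with one term enriched in true hits.

    The planted term draws ``planted_hit_frac`` of its members from the
    true-sensitive strains; the remaining terms are uniform draws from the
    whole library.  Returns ``{term_id: (term_name, members)}`` — the
    shape of a parsed GMT file.
    """
    rng = np.random.default_rng(seed)
    universe = list(truth["strain_id"])
    sens = list(truth.loc[truth["true_class"] == CLASS_SENSITIVE, "strain_id"])
    n_from_hits = min(int(round(planted_size * planted_hit_frac)), len(sens))
    members = list(rng.choice(sens, n_from_hits, replace=False))
    others = [s for s in universe if s not in set(members)]
    members += list(rng.choice(others, planted_size - n_from_hits, replace=False))
    sets = {planted_term: ("planted enriched module", members)}
    for i in range(n_random_terms):
        sets[f"RND:{i:03d}"] = (
            f"random term {i}",
            list(rng.choice(universe, term_size, replace=False)),
        )
    return sets
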