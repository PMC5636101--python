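"""Synthetic telemetry: landscapes, covariate-modulated two-state tracks, accelerometry.

The generator emulates the study design so every downstream stage is testable
without field data: weekly 24-hour intensive sampling periods at a 15-minute
cadence (96 fixes, 95 segments), a two-state (active/inactive) latent
behavior process whose transition probabilities depend on day/night, house
proximity (≤150 m), habitat and sex, state-dependent step lengths, matched
accelerometer activity fractions, and ODBA-style per-interval energy.

Movement is deliberately a state-switching random walk reflected at the
arena boundary — no home-range mechanics — which is sufficient to exercise
every downstream statistic.  The latent chain's covariates are evaluated at
the junction fix (the GPS acquisition between two intervals), exactly where
the analysis pipeline later reads them, so per-stratum transition counts are
directly comparable between generator truth and pipeline output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from puma_energetics.annotate import classify_periods
from puma_energetics.config import StudyConfig
from puma_energetics.energetics import DEFAULT_PARAMS, day_raw_kcal_per_kg
from puma_energetics.io import HabitatLayer, HouseLayer

STATE_I, STATE_A = 0, 1  # inactive, active


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class Zone:
    """Axis-aligned rectangle with a homogeneous Poisson house density."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    density_ha: float

    @property
    def area_ha(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min) / 1e4


@dataclass
class LandscapeSpec:
    """Rectangular arena with housing zones and a vertical-strip habitat mosaic."""

    width_m: float = 2000.0
    height_m: float = 2000.0
    zones: list = None
    #: (x_min, x_max, label) strips; must tile [0, width_m]
    habitat_strips: list = None

    def __post_init__(self) -> None:
        if self.zones is None:
            # undeveloped west half, exurban-density east half
            self.zones = [
                Zone(0.0, self.width_m / 2, 0.0, self.height_m, 0.0),
                Zone(self.width_m / 2, self.width_m, 0.0, self.height_m, 0.3),
            ]
        if self.habitat_strips is None:
            self.habitat_strips = [(0.0, self.width_m, "forest")]


@dataclass
class TransitionModel:
    """Baseline transition probabilities plus logit offsets on P(next = active).

    The baseline applies to the reference stratum (day, far from houses,
    forest, female); offsets shift the logit of becoming/staying active.
    Defaults encode the study's qualitative structure: generally higher
    nighttime activity, a further activity increase near houses at night, and
    suppressed activity near houses during the day.
    """

    p_ia: float = 0.04  # baseline P(inactive -> active)
    p_ai: float = 0.50  # baseline P(active -> inactive)
    night_offset: float = 0.5
    night_house_offset: float = 0.6
    day_house_offset: float = -0.4
    shrubland_offset: float = -0.25
    male_offset: float = 0.35

    def __post_init__(self) -> None:
        if not (0 < self.p_ia < 1 and 0 < self.p_ai < 1):
            raise ValueError("baseline transition probabilities must lie in (0, 1)")

    def offset(self, night: bool, near_house: bool, shrubland: bool, male: bool) -> float:
        off = 0.0
        if night:
            off += self.night_offset
        if near_house:
            off += self.night_house_offset if night else self.day_house_offset
        if shrubland:
            off += self.shrubland_offset
        if male:
            off += self.male_offset
        return off

    def p_active(
        self, prev_active: bool, night: bool, near_house: bool, shrubland: bool, male: bool
    ) -> float:
        """P(next interval active | previous state and junction covariates)."""
        base = (1.0 - self.p_ai) if prev_active else self.p_ia
        return _expit(_logit(base) + self.offset(night, near_house, shrubland, male))

    def matrix(self, night: bool, near_house: bool, shrubland: bool, male: bool) -> np.ndarray:
        """Row-stochastic 2x2 matrix (rows inactive, active) for one stratum."""
        q = self.p_active(False, night, near_house, shrubland, male)
        s = self.p_active(True, night, near_house, shrubland, male)
        return np.array([[1.0 - q, q], [1.0 - s, s]])

    def stationary_active(
        self, night: bool, near_house: bool, shrubland: bool, male: bool
    ) -> float:
        """Closed-form stationary activity proportion of one stratum's chain."""
        q = self.p_active(False, night, near_house, shrubland, male)
        s = self.p_active(True, night, near_house, shrubland, male)
        return q / (q + (1.0 - s))


@dataclass
class StepModel:
    """State-dependent step lengths: half-normal (inactive), gamma (active)."""

    inactive_mean_m: float = 15.0
    active_mean_m: float = 300.0
    active_shape: float = 5.0

    def __post_init__(self) -> None:
        if not self.inactive_mean_m < self.active_mean_m:
            raise ValueError("inactive step mean must be below the active mean")

    @property
    def inactive_sigma(self) -> float:
        # half-normal mean = sigma * sqrt(2/pi)
        return self.inactive_mean_m / math.sqrt(2.0 / math.pi)

    @property
    def active_scale(self) -> float:
        return self.active_mean_m / self.active_shape


@dataclass
class AccelModel:
    """Beta-distributed activity fractions per 15-min interval, by state."""

    active_a: float = 8.0
    active_b: float = 8.0  # mean 0.5, well above the 10% cutoff
    inactive_a: float = 2.0
    inactive_b: float = 48.0  # mean 0.04, well below the cutoff


@dataclass
class OdbaModel:
    """Per-interval ODBA energy: a + b × raw interval kcal/kg + Gaussian noise."""

    intercept: float = 8.21 / 96.0
    slope: float = 1.88
    sigma: float = 0.02


@dataclass
class AnimalSpec:
    animal_id: str
    sex: str  # "F" or "M"
    body_mass_kg: float
    start_xy: tuple[float, float] | None = None  # default: uniform in the arena


@dataclass
class SimScenario:
    """Study conditions for the generator.

    Defaults mirror the field study: 11 males and 11 females (masses 53.3 ±
    7.8 and 39.8 ± 2.7 kg), weekly 24-h intensive periods starting at local
    noon, and 17 monitored days per animal (≈ the study's 369 accepted
    energetic days over 19 animals).
    """

    n_males: int = 11
    n_females: int = 11
    n_days: int = 17
    male_mass_kg: float = 53.3
    male_mass_sd: float = 7.82
    female_mass_kg: float = 39.8
    female_mass_sd: float = 2.73
    landscape: LandscapeSpec = field(default_factory=LandscapeSpec)
    transition: TransitionModel = field(default_factory=TransitionModel)
    steps: StepModel = field(default_factory=StepModel)
    accel: AccelModel = field(default_factory=AccelModel)
    odba: OdbaModel = field(default_factory=OdbaModel)
    start: str = "2011-01-03"  # first sampling period start date (local)

    def animals(self, rng: np.random.Generator) -> list[AnimalSpec]:
        out = []
        for i in range(self.n_females):
            mass = max(float(rng.normal(self.female_mass_kg, self.female_mass_sd)), 20.0)
            out.append(AnimalSpec(f"{i + 1:02d}F", "F", mass))
        for i in range(self.n_males):
            mass = max(float(rng.normal(self.male_mass_kg, self.male_mass_sd)), 25.0)
            out.append(AnimalSpec(f"{i + 1 + self.n_females:02d}M", "M", mass))
        return out


@dataclass
class SimTruth:
    """Ground truth for one simulated track.

    ``states`` holds the latent interval states (0/1) per day;
    ``transition_counts`` is a (2,2,2,2) array over (B, A, H, T) realized at
    junction fixes; ``day_distance_m``/``day_raw_kcal_per_kg`` are the true
    per-day totals from the generator's own step lengths.
    """

    animal_id: str
    sex: str
    body_mass_kg: float
    states: list
    transition_counts: np.ndarray
    day_distance_m: list
    day_raw_kcal_per_kg: list

    @property
    def n_transitions(self) -> int:
        return int(self.transition_counts.sum())


def generate_landscape(
    spec: LandscapeSpec, seed: int | np.random.Generator
) -> tuple[HouseLayer, HabitatLayer]:
    """Homogeneous-Poisson house placement per zone plus the habitat mosaic."""
    rng = np.random.default_rng(seed)
    pts = []
    for zone in spec.zones:
        if zone.area_ha <= 0:
            raise ValueError("zero-area housing zone")
        if zone.density_ha < 0:
            raise ValueError("house density cannot be negative")
        n = rng.poisson(zone.density_ha * zone.area_ha)
        if n:
            xs = rng.uniform(zone.x_min, zone.x_max, n)
            ys = rng.uniform(zone.y_min, zone.y_max, n)
            pts.append(np.column_stack([xs, ys]))
    houses = HouseLayer(np.vstack(pts) if pts else np.empty((0, 2)))
    polys = [
        (box(x0, 0.0, x1, spec.height_m), label) for x0, x1, label in spec.habitat_strips
    ]
    return houses, HabitatLayer(polys)


def _habitat_at(x: float, strips) -> str:
    for x0, x1, label in strips:
        if x0 <= x <= x1:
            return label
    raise ValueError(f"x = {x} outside the habitat mosaic")


def simulate_track(
    scenario: SimScenario,
    landscape: tuple[HouseLayer, HabitatLayer] | HouseLayer,
    animal: AnimalSpec,
    seed: int | np.random.Generator,
    config: StudyConfig | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate one animal's weekly intensive sampling periods.

    Returns the fix table (96 fixes per day; columns animal_id, timestamp,
    x, y, sex, body_mass_kg, activity_fraction, odba_kcal_per_kg) and the
    generator truth.  ``activity_fraction``/``odba_kcal_per_kg`` at a fix
    describe the following 15-minute interval (NaN on each day's last fix).
    """
    rng = np.random.default_rng(seed)
    config = config or StudyConfig()
    houses = landscape[0] if isinstance(landscape, tuple) else landscape
    spec = scenario.landscape
    tm, sm, am, om = scenario.transition, scenario.steps, scenario.accel, scenario.odba
    male = animal.sex == "M"
    tree = houses.tree
    r_buf = config.buffer_radius_m
    n_fix = config.fixes_per_day
    dt = config.fix_interval_s
    params = DEFAULT_PARAMS
    cl = params.loco_w_per_kg_per_mps(animal.body_mass_kg)
    cp = params.postural_w_per_kg(animal.body_mass_kg)

    start_local = pd.Timestamp(scenario.start) + pd.Timedelta(hours=config.period_start_hour)
    start_utc = (start_local - pd.Timedelta(hours=config.utc_offset_hours)).tz_localize("UTC")

    if animal.start_xy is not None:
        pos = np.asarray(animal.start_xy, dtype=float)
    else:
        pos = np.array([rng.uniform(0, spec.width_m), rng.uniform(0, spec.height_m)])
    counts = np.zeros((2, 2, 2, 2))  # B, A, H, T
    all_rows = []
    states_by_day = []
    day_dist = []
    day_kcal = []
    n_steps = n_fix - 1
    for d in range(scenario.n_days):
        t0 = start_utc + pd.Timedelta(days=7 * d)
        times = t0 + pd.to_timedelta(np.arange(n_fix) * dt, unit="s")
        periods = classify_periods(times, config)
        night = periods == "night"
        u_trans = rng.random(n_steps)
        angles = rng.uniform(0.0, 2.0 * math.pi, n_steps)
        step_inact = np.abs(rng.normal(0.0, sm.inactive_sigma, n_steps))
        step_act = rng.gamma(sm.active_shape, sm.active_scale, n_steps)
        frac_act = rng.beta(am.active_a, am.active_b, n_steps)
        frac_inact = rng.beta(am.inactive_a, am.inactive_b, n_steps)
        odba_noise = rng.normal(0.0, om.sigma, n_steps)

        xs = np.empty(n_fix)
        ys = np.empty(n_fix)
        xs[0], ys[0] = pos
        states = np.empty(n_steps, dtype=np.int8)
        # initial interval state drawn from the stationary budget at the start fix
        hab0 = _habitat_at(pos[0], spec.habitat_strips)
        near0 = _near_house(tree, pos, r_buf)
        p0 = tm.stationary_active(bool(night[0]), near0, hab0 == "shrubland", male)
        state = STATE_A if rng.random() < p0 else STATE_I
        dist_total = 0.0
        for i in range(n_steps):
            states[i] = state
            step = step_act[i] if state == STATE_A else step_inact[i]
            new = pos + step * np.array([math.cos(angles[i]), math.sin(angles[i])])
            new[0] = _reflect(new[0], spec.width_m)
            new[1] = _reflect(new[1], spec.height_m)
            dist_total += float(np.hypot(*(new - pos)))
            pos = new
            xs[i + 1], ys[i + 1] = pos
            if i < n_steps - 1:
                # transition into the next interval, covariates at junction fix i+1
                near = _near_house(tree, pos, r_buf)
                hab = _habitat_at(pos[0], spec.habitat_strips)
                is_night = bool(night[i + 1])
                p_act = tm.p_active(state == STATE_A, is_night, near, hab == "shrubland", male)
                nxt = STATE_A if u_trans[i] < p_act else STATE_I
                counts[state, nxt, int(near), int(is_night)] += 1
                state = nxt
        activity = np.where(states == STATE_A, frac_act, frac_inact)
        raw_interval = (cl * np.hypot(np.diff(xs), np.diff(ys)) + cp * dt) / params.joules_per_kcal
        odba = om.intercept + om.slope * raw_interval + odba_noise
        all_rows.append(
            pd.DataFrame(
                {
                    "animal_id": animal.animal_id,
                    "timestamp": times,
                    "x": xs,
                    "y": ys,
                    "sex": animal.sex,
                    "body_mass_kg": animal.body_mass_kg,
                    "activity_fraction": np.append(activity, np.nan),
                    "odba_kcal_per_kg": np.append(odba, np.nan),
                }
            )
        )
        states_by_day.append(states)
        day_dist.append(dist_total)
        day_kcal.append(day_raw_kcal_per_kg(dist_total, animal.body_mass_kg, params))
    track = pd.concat(all_rows, ignore_index=True)
    truth = SimTruth(
        animal_id=animal.animal_id,
        sex=animal.sex,
        body_mass_kg=animal.body_mass_kg,
        states=states_by_day,
        transition_counts=counts,
        day_distance_m=day_dist,
        day_raw_kcal_per_kg=day_kcal,
    )
    return track, truth


def _near_house(tree, pos: np.ndarray, radius: float) -> bool:
    if tree is None:
        return False
    d, _ = tree.query(pos)
    return bool(d <= radius)


def _reflect(v: float, bound: float) -> float:
    period = 2.0 * bound
    v = v % period
    return period - v if v > bound else v


def simulate_dataset(
    scenario: SimScenario, seed: int, config: StudyConfig | None = None
) -> tuple[pd.DataFrame, HouseLayer, HabitatLayer, dict]:
    """Simulate the full scenario: landscape plus one track per animal.

    Returns (fixes, houses, habitat, truths) with truths keyed by animal id.
    All randomness descends from ``seed``; identical seeds give bit-identical
    outputs.
    """
    rng = np.random.default_rng(seed)
    houses, habitat = generate_landscape(scenario.landscape, rng)
    truths: dict[str, SimTruth] = {}
    tracks = []
    for animal in scenario.animals(rng):
        track, truth = simulate_track(scenario, (houses, habitat), animal, rng, config)
        tracks.append(track)
        truths[animal.animal_id] = truth
    return pd.concat(tracks, ignore_index=True), houses, habitat, truths


def degrade_track(track: pd.DataFrame, missingness: float, seed: int) -> pd.DataFrame:
    """Drop fixes independently with probability ``missingness``, keeping order."""
    if not 0 <= missingness < 1:
        raise ValueError("missingness must lie in [0, 1)")
    if missingness == 0:
        return track.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(len(track)) >= missingness
    return track[keep].reset_index(drop=True)
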