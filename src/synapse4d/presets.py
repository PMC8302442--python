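"""Per-condition generative presets for the OTI CTL / EL4 APL system.

Each preset encodes the latent statistics of CTL-target killing choreography
for one altered peptide ligand (APL) pulsed onto targets:

* ``N4`` (SIINFEKL)  - strong agonist
* ``T4`` (SIITFEKL)  - intermediate
* ``G4`` (SIIGFEKL)  - weak agonist
* ``NP68``           - irrelevant peptide (no TCR signal)

Calibration targets (the published population statistics the generator is
built to reproduce):

==========================================  =====  =====  =====  =====
statistic                                    N4     T4     G4    NP68
==========================================  =====  =====  =====  =====
mean interactions / CTL / 40 min             4.03   4.77   5.63   6.8*
docked fraction of conjugates by 600 s       0.80   0.55   0.20   0
docked fraction of conjugates by 750 s       1.00   0.66   0.30   0
median primary Ca2+ flux duration (s)        100    ~80*    60     30
==========================================  =====  =====  =====  =====

(*) not printed anywhere; chosen to preserve the across-condition ordering.

Shared, condition-independent structure: docked cells draw their primary
flux duration from LogNormal(median 190 s, sigma 0.414, >=50 s), giving a
docked-group mean of 207 s; non-docked cells draw ~60 s-mean fluxes.  The
condition-level medians above then emerge purely from each condition's
docked fraction - the biology being that signal strength sets the *rate* at
which cells enter a conserved program, not the program itself.

The first-flux onset latency is a 50/50 fast/slow log-normal mixture,
matching simultaneously: 42% of fluxes within 30 s of contact, median 46 s
and mean 55 s (no single log-normal satisfies all three).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .distributions import Beta, LogNormal, LogNormalMixture, Uniform

__all__ = ["ConditionPreset", "make_preset", "CONDITIONS"]

CONDITIONS = ("N4", "T4", "G4", "NP68")

#: centrosome approach speed, um/s; constant across presets (timing and
#: maximum speed of centrosome movement do not vary with signal strength)
APPROACH_SPEED_UM_S = 0.05

#: minimum dwell (s) for an interaction to count as a stable conjugate
STABLE_CONJUGATE_MIN_DWELL_S = 120.0

#: first-flux onset latency after contact, shared across conditions:
#: P(<=30 s) = 0.423, median ~45.6 s, mean ~55.7 s
FLUX_ONSET_LATENCY = LogNormalMixture(
    weight=0.5,
    a=LogNormal(median=19.0, sigma=0.45),
    b=LogNormal(median=85.0, sigma=0.35),
)

#: primary flux duration for cells whose centrosome docks: mean 207 s,
#: median 190 s, never below 50 s -- identical in every condition
FLUX_DURATION_DOCKED = LogNormal(median=190.0, sigma=0.414, low=50.0)

#: flux-onset -> uropod-retraction latency (mean 91.7 s, median 66.5 s)
UROPOD_LATENCY = LogNormal(median=66.5, sigma=0.80)

#: flux-onset -> start-of-centrosome-polarisation latency (mean 94 s,
#: median 70 s)
POLARISATION_LATENCY = LogNormal(median=70.0, sigma=0.77)


@dataclass(frozen=True)
class ConditionPreset:
    """Latent per-condition parameters driving the synthetic generator."""

    condition_name: str
    #: dwell time per interaction (s); log-normal, right-skewed
    dwell_time_dist: LogNormal
    #: mean number of contact episodes per CTL per 40 min
    contacts_per_ctl_mean: float
    #: probability an interaction is a stable conjugate (dwell >= 120 s);
    #: equals P(dwell >= 120 s) under dwell_time_dist
    p_stable_conjugate: float
    #: contact -> centrosome-docking latency for docking conjugates (s)
    docking_time_dist: LogNormal | None
    #: probability a stable conjugate ever docks its centrosome
    p_dock: float
    #: first-flux onset latency after contact (s)
    flux_onset_latency_dist: LogNormalMixture = FLUX_ONSET_LATENCY
    #: primary flux duration for docking cells (s)
    flux_duration_docked_dist: LogNormal = FLUX_DURATION_DOCKED
    #: primary flux duration for non-docking cells (s)
    flux_duration_nondocked_dist: LogNormal = LogNormal(55.0, 0.385)
    #: P(>=1 granule delivered <0.5 um of synapse | centrosome docked)
    p_concomitant_delivery_given_dock: float = 0.93
    n_granules: int = 8
    granule_cluster_radius_um: float = 1.5
    #: true depleted synapse-area fraction for fixed conjugate stacks
    depletion_fraction_dist: Beta = field(default_factory=lambda: Beta(3.0, 7.0))
    #: closest-approach mix for stable-but-never-docked conjugates
    #: (proximal, distal, uropod)
    nondock_class_probs: tuple[float, float, float] = (0.50, 0.35, 0.15)
    #: flux-onset ordering latencies, shared
    uropod_latency_dist: LogNormal = UROPOD_LATENCY
    polarisation_latency_dist: LogNormal = POLARISATION_LATENCY
    approach_speed_um_s: float = APPROACH_SPEED_UM_S

    def __post_init__(self):
        for p in (self.p_stable_conjugate, self.p_dock,
                  self.p_concomitant_delivery_given_dock):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.contacts_per_ctl_mean < 0:
            raise ValueError("contacts_per_ctl_mean must be >= 0")
        if self.p_dock > 0 and self.docking_time_dist is None:
            raise ValueError("docking preset required when p_dock > 0")

    @property
    def docked_interaction_fraction(self) -> float:
        """P(an interaction docks) = P(stable) * P(dock | stable)."""
        return self.p_stable_conjugate * self.p_dock

    def population_flux_median(self) -> float:
        """Median primary flux duration over all interactions (s).

        The population is a two-component mixture (docked / non-docked);
        the median is found by bisection on the mixture CDF.
        """
        q = self.docked_interaction_fraction

        def cdf(x):
            return (q * self.flux_duration_docked_dist.cdf(x)
                    + (1 - q) * self.flux_duration_nondocked_dist.cdf(x))

        lo, hi = 1.0, 2000.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if cdf(mid) < 0.5:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)


_PRESETS: dict[str, dict] = {
    # dwell medians give P(dwell >= 120 s) = p_stable below (sigma 0.8)
    "N4": dict(
        dwell_time_dist=LogNormal(120.0, 0.8, low=25.0),
        contacts_per_ctl_mean=4.03,
        p_stable_conjugate=0.500,
        # P(dock <= 600 s) = 0.80, P(<= 750 s) = 0.954
        docking_time_dist=LogNormal(480.0, 0.265),
        p_dock=1.0,
        flux_duration_nondocked_dist=LogNormal(55.0, 0.385),
        granule_cluster_radius_um=1.2,
        depletion_fraction_dist=Beta(4.5, 5.5),   # mean 0.45
    ),
    "T4": dict(
        dwell_time_dist=LogNormal(90.0, 0.8, low=25.0),
        contacts_per_ctl_mean=4.77,
        p_stable_conjugate=0.360,
        # p_dock * P(dock <= 600) = 0.55; * P(<= 750) = 0.66
        docking_time_dist=LogNormal(480.0, 0.28),
        p_dock=0.70,
        flux_duration_nondocked_dist=LogNormal(56.0, 0.385),
        granule_cluster_radius_um=1.5,
        depletion_fraction_dist=Beta(3.5, 6.5),   # mean 0.35
    ),
    "G4": dict(
        dwell_time_dist=LogNormal(70.0, 0.8, low=25.0),
        contacts_per_ctl_mean=5.63,
        p_stable_conjugate=0.250,
        # p_dock * P(dock <= 600) = 0.20; * P(<= 750) = 0.27
        docking_time_dist=LogNormal(560.0, 0.38),
        p_dock=0.35,
        flux_duration_nondocked_dist=LogNormal(57.0, 0.385),
        granule_cluster_radius_um=1.9,
        depletion_fraction_dist=Beta(2.5, 7.5),   # mean 0.25
    ),
    "NP68": dict(
        dwell_time_dist=LogNormal(35.0, 0.8, low=25.0),
        contacts_per_ctl_mean=6.8,
        p_stable_conjugate=0.062,
        docking_time_dist=None,
        p_dock=0.0,
        flux_duration_nondocked_dist=LogNormal(30.0, 0.385),
        granule_cluster_radius_um=2.0,
        depletion_fraction_dist=Beta(1.2, 10.8),  # mean 0.10
    ),
}


def make_preset(condition_name: str, **overrides) -> ConditionPreset:
    """Return the documented default preset for ``condition_name``.

    ``overrides`` replace individual fields (``custom`` requires a full set
    of generative fields to be supplied).

    Raises
    ------
    ValueError
        If the condition name is not one of N4, T4, G4, NP68 or custom.
    """
    if condition_name == "custom":
        base = dict(_PRESETS["N4"])
        base.update(overrides)
        return ConditionPreset(condition_name="custom", **base)
    if condition_name not in _PRESETS:
        raise ValueError(
            f"unknown condition {condition_name!r}; expected one of "
            f"{CONDITIONS + ('custom',)}"
        )
    cfg = dict(_PRESETS[condition_name])
    cfg.update(overrides)
    return ConditionPreset(condition_name=condition_name, **cfg)
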