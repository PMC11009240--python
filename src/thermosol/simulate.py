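"""Synthetic-data generators with known ground truth for every pipeline input.

Each generator is the explicit generative counterpart of an inference stage:
fractionation triplets come from latent true pSups and per-experiment mixing
ratios under lognormal (optionally negative-binomial) noise; growth curves
follow the cardinal temperature model; heat-shock-response curves are
amplitude-scaled skew-normal densities; DLS ramps are flat monomer baselines
with a linear post-onset rise; HDX peptide tables tile a protein whose
per-site exchange fractions are programmed per state, with point-mutated
"orthologs"; regulon fold-change tables add regulator-level effects to
per-gene noise.  Every generator takes a seed and returns a truth record, so
recovery can be measured exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from thermosol.thermal import ctmi_value, skewnormal_mode

__all__ = [
    "SimScenario",
    "FractionationTruth",
    "default_scenario",
    "simulate_fractionation",
    "simulate_growth",
    "simulate_dls_ramp",
    "simulate_hsr_curve",
    "simulate_hdx",
    "simulate_regulons",
]

AA_NO_PRO = "ACDEFGHIKLMNQRSTVWY"  # proline excluded: no amide proton


@dataclass
class SimScenario:
    """Class-structured fractionation scenario.

    ``class_spec`` maps a class label to
    ``(count, (a, b) basal Beta params, (a, b) shocked Beta params)`` for
    the latent pSup distribution of that class under each condition.
    ``noise_model`` is ``"lognormal"`` (noise on the total only, matching
    the inference likelihood) or ``"negative_binomial"`` (S and P
    additionally resampled with dispersion ``nb_dispersion``; variance
    m + m^2/k).
    """

    n_proteins: int
    class_spec: dict
    noise_model: str = "lognormal"
    nb_dispersion: float = 10.0
    abundance_meanlog: float = 8.0
    abundance_sdlog: float = 1.5

    def __post_init__(self):
        total = sum(count for count, _, _ in self.class_spec.values())
        if total != self.n_proteins:
            raise ValueError(
                f"class counts sum to {total}, expected {self.n_proteins}"
            )
        if self.noise_model not in ("lognormal", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_proteins < 1:
            raise ValueError("empty scenario")


@dataclass
class FractionationTruth:
    """Latent ground truth behind one simulated fractionation experiment."""

    true_psup: np.ndarray
    alpha_s_true: float
    alpha_p_true: float
    sigma_true: float
    abundance: np.ndarray
    protein_class: np.ndarray
    seed: int

    def __post_init__(self):
        self.true_psup = np.asarray(self.true_psup, float)
        if self.true_psup.min() < 0 or self.true_psup.max() > 1:
            raise ValueError("true pSup outside [0, 1]")
        if min(self.alpha_s_true, self.alpha_p_true) <= 0 or self.sigma_true < 0:
            raise ValueError("mixing ratios must be > 0 and sigma >= 0")

    def to_frame(self) -> pd.DataFrame:
        n = self.true_psup.size
        return pd.DataFrame(
            {
                "protein_id": [f"prot{i:05d}" for i in range(n)],
                "true_psup": self.true_psup,
                "abundance": self.abundance,
                "protein_class": self.protein_class,
            }
        )


def default_scenario(
    n_proteins: int = 2000,
    frac_condensers: float = 0.3,
    noise_model: str = "lognormal",
    nb_dispersion: float = 10.0,
) -> SimScenario:
    """Two-class scenario mimicking proteome-wide condensation geometry.

    Condensers are soluble at basal temperature (pSup ~ Beta(20, 2)) and
    pelleted after shock (Beta(2, 20)); non-condensers stay soluble in both
    conditions.
    """
    n_cond = int(round(frac_condensers * n_proteins))
    return SimScenario(
        n_proteins=n_proteins,
        class_spec={
            "condenser": (n_cond, (20.0, 2.0), (2.0, 20.0)),
            "noncondenser": (n_proteins - n_cond, (20.0, 2.0), (20.0, 2.0)),
        },
        noise_model=noise_model,
        nb_dispersion=nb_dispersion,
    )


def simulate_fractionation(
    scenario: SimScenario,
    alpha_s: float,
    alpha_p: float,
    sigma: float,
    seed: int,
    condition: str = "basal",
    species: str = "simyeast",
    replicate: int = 1,
    temperature_c: float = 30.0,
    true_psup=None,
) -> tuple[pd.DataFrame, FractionationTruth]:
    """Generate one fractionation experiment (T/S/P per protein) plus truth.

    The generative model is the exact inverse of the inference model::

        S_i = A_i * pSup_i / alpha_s
        P_i = A_i * (1 - pSup_i) / alpha_p
        T_i = A_i * exp(eps_i),   eps_i ~ Normal(0, sigma)

    so that alpha_s*S_i + alpha_p*P_i = A_i and
    log T_i - log(alpha_s*S_i + alpha_p*P_i) ~ Normal(0, sigma).  Under the
    negative-binomial option S and P are additionally resampled as
    gamma-Poisson mixtures with the scenario's dispersion.  ``condition``
    selects the basal or shocked pSup distribution per class; passing
    ``true_psup`` instead imposes given latent pSups (e.g. to simulate two
    species sharing condition-specific solubilities).
    """
    if alpha_s <= 0 or alpha_p <= 0 or sigma < 0:
        raise ValueError("alpha_s, alpha_p must be > 0 and sigma >= 0")
    if condition not in ("basal", "shocked"):
        raise ValueError("condition must be 'basal' or 'shocked'")
    rng = np.random.default_rng(seed)

    classes = []
    for label, (count, _, _) in scenario.class_spec.items():
        classes.extend([label] * count)
    classes = np.asarray(classes, object)
    if true_psup is not None:
        true_psup = np.asarray(true_psup, float)
        if true_psup.size != scenario.n_proteins:
            raise ValueError("true_psup length does not match the scenario")
    else:
        psups = []
        for label, (count, basal_ab, shocked_ab) in scenario.class_spec.items():
            a, b = basal_ab if condition == "basal" else shocked_ab
            psups.append(rng.beta(a, b, size=count))
        true_psup = np.concatenate(psups)

    abundance = rng.lognormal(
        scenario.abundance_meanlog, scenario.abundance_sdlog, scenario.n_proteins
    )
    sup = abundance * true_psup / alpha_s
    pellet = abundance * (1.0 - true_psup) / alpha_p
    eps = rng.normal(0.0, sigma, scenario.n_proteins) if sigma > 0 else 0.0
    total = abundance * np.exp(eps)

    if scenario.noise_model == "negative_binomial":
        k = scenario.nb_dispersion
        sup = rng.poisson(rng.gamma(k, np.maximum(sup, 1e-12) / k)).astype(float)
        pellet = rng.poisson(rng.gamma(k, np.maximum(pellet, 1e-12) / k)).astype(
            float
        )

    quant = pd.DataFrame(
        {
            "protein_id": [f"prot{i:05d}" for i in range(scenario.n_proteins)],
            "species": species,
            "condition": condition,
            "temperature_c": temperature_c,
            "replicate": replicate,
            "total": total,
            "sup": sup,
            "pellet": pellet,
        }
    )
    truth = FractionationTruth(
        true_psup=true_psup,
        alpha_s_true=alpha_s,
        alpha_p_true=alpha_p,
        sigma_true=sigma,
        abundance=abundance,
        protein_class=classes,
        seed=seed,
    )
    return quant, truth


def simulate_growth(
    t_min: float,
    t_opt: float,
    t_max: float,
    mu_opt: float,
    temperatures,
    od0: float = 0.05,
    times=None,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """OD600 time courses following CTMI exponential growth.

    ``OD(t) = od0 * exp(mu(T) * t/60) * (1 + noise)`` with ``mu(T)`` from the
    cardinal temperature model (per hour; times in minutes) and
    multiplicative Gaussian noise of coefficient of variation ``noise_cv``.
    Outside [t_min, t_max] the growth rate is zero and OD stays at od0.
    """
    if not (t_min < t_opt < t_max):
        raise ValueError("cardinal ordering t_min < t_opt < t_max required")
    if times is None:
        times = np.arange(0.0, 481.0, 30.0)
    times = np.asarray(times, float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    rows = []
    for temp in np.atleast_1d(np.asarray(temperatures, float)):
        mu = ctmi_value(float(temp), t_min, t_opt, t_max, mu_opt)
        od = od0 * np.exp(mu * times / 60.0)
        if noise_cv > 0:
            od = od * (1.0 + noise_cv * rng.standard_normal(times.size))
        rows.append(
            pd.DataFrame(
                {
                    "temperature_c": temp,
                    "time_min": times,
                    "od600": np.maximum(od, 1e-6),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_dls_ramp(
    baseline_rh: float,
    t_onset: float,
    post_onset_slope: float,
    t_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicate: int = 1,
    protein: str = "Pab1",
) -> pd.DataFrame:
    """DLS temperature ramp: flat monomer baseline, then linear growth.

    ``R_h(T) = baseline_rh + post_onset_slope * max(0, T - t_onset)`` plus
    Gaussian noise of SD ``noise_sd`` (nm).
    """
    t_grid = np.asarray(t_grid, float)
    if baseline_rh <= 0:
        raise ValueError("baseline_rh must be > 0")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing")
    if not (t_grid.min() <= t_onset <= t_grid.max()):
        raise ValueError("t_onset outside the temperature grid")
    rng = np.random.default_rng(seed)
    rh = baseline_rh + post_onset_slope * np.maximum(0.0, t_grid - t_onset)
    if noise_sd > 0:
        rh = rh + noise_sd * rng.standard_normal(t_grid.size)
    return pd.DataFrame(
        {
            "protein": protein,
            "replicate": replicate,
            "temperature_c": t_grid,
            "rh_nm": np.maximum(rh, 1e-3),
        }
    )


def simulate_hsr_curve(
    xi: float,
    omega: float,
    alpha_shape: float,
    amplitude: float,
    temperatures,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Heat-shock-response curve: amplitude-scaled skew-normal density.

    ``response(T) = amplitude * f(T; xi, omega, alpha) / f(mode)`` plus
    Gaussian noise (same fold units as the amplitude), one point per
    temperature.
    """
    from scipy import stats

    if omega <= 0:
        raise ValueError("omega must be > 0")
    temperatures = np.asarray(temperatures, float)
    rng = np.random.default_rng(seed)
    if amplitude == 0:
        response = np.zeros(temperatures.size)
    else:
        dens = stats.skewnorm.pdf(temperatures, alpha_shape, loc=xi, scale=omega)
        mode = skewnormal_mode(xi, omega, alpha_shape, grid_step=0.001)
        peak = stats.skewnorm.pdf(mode, alpha_shape, loc=xi, scale=omega)
        response = amplitude * dens / peak
    if noise_sd > 0:
        response = response + noise_sd * rng.standard_normal(temperatures.size)
    return pd.DataFrame({"temperature_c": temperatures, "response_fold": response})


def _mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i, aa in enumerate(out):
        if aa != "P" and rng.random() < rate:
            choices = [c for c in AA_NO_PRO if c != aa]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def simulate_hdx(
    protection_profile: dict,
    peptide_len_range: tuple[int, int] = (8, 16),
    tiling_step: int = 5,
    mutation_rate: float = 0.0,
    n_orthologs: int = 2,
    noise_sd: float = 0.0,
    seed: int = 0,
    profile_jitter_sd: float = 0.0,
    timepoint_s: float = 100.0,
) -> tuple[pd.DataFrame, dict, dict]:
    """Peptide-tiled HDX tables for mutationally diverged "orthologs".

    ``protection_profile`` maps a state name (e.g. monomer, condensate) to a
    per-site exchange fraction array in [0, 1]; all states share one
    length.  A random base sequence of that length is tiled by peptides
    (lengths uniform in ``peptide_len_range``, starts every
    ``tiling_step``), and each peptide's %D is the mean of its covered
    sites' true fractions x 100 plus Gaussian noise.  Covered sites follow
    HDX convention (first residue and prolines excluded).  Orthologs are
    point-mutated copies sharing the (optionally jittered) profile.

    Returns ``(peptide table, {ortholog: sequence}, truth)`` where truth
    maps ``(ortholog, state)`` to the per-site true fraction array actually
    used (post-jitter).
    """
    from thermosol.hdx import _covered_sites

    profiles = {k: np.asarray(v, float) for k, v in protection_profile.items()}
    lengths = {v.size for v in profiles.values()}
    if len(lengths) != 1:
        raise ValueError("all state profiles must share one length")
    (length,) = lengths
    for state, vals in profiles.items():
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError(f"profile for {state!r} outside [0, 1]")
    lo, hi = peptide_len_range
    if lo < 2 or hi < lo:
        raise ValueError("invalid peptide length range")

    rng = np.random.default_rng(seed)
    base_seq = "".join(
        AA_NO_PRO[i] for i in rng.integers(len(AA_NO_PRO), size=length)
    )
    # plant sparse prolines away from position 1 so the exclusion rule is
    # live on realistic protein lengths (none on very short toy inputs)
    n_pro = length // 30
    if n_pro:
        seq_list = list(base_seq)
        for pos in rng.choice(np.arange(2, length), size=n_pro, replace=False):
            seq_list[pos] = "P"
        base_seq = "".join(seq_list)

    sequences, truth, rows = {}, {}, []
    for o in range(n_orthologs):
        name = f"ortholog{o + 1}"
        seq = base_seq if o == 0 else _mutate_sequence(base_seq, mutation_rate, rng)
        sequences[name] = seq
        for state, vals in profiles.items():
            used = vals.copy()
            if profile_jitter_sd > 0 and o > 0:
                used = np.clip(
                    used + profile_jitter_sd * rng.standard_normal(length), 0, 1
                )
            truth[(name, state)] = used
            start = 1
            while start <= length:
                plen = int(rng.integers(lo, hi + 1))
                end = min(start + plen - 1, length)
                if length - end < lo:  # absorb a short tail into the last peptide
                    end = length
                sites = _covered_sites(start, end, seq, True, True)
                if sites:
                    frac = float(np.mean(used[[s - 1 for s in sites]]))
                    pct = 100.0 * frac + (
                        noise_sd * rng.standard_normal() if noise_sd > 0 else 0.0
                    )
                    pct = float(np.clip(pct, 0.0, 100.0))
                    n_ex = len(sites)
                    mass_undeut = 800.0 + 110.0 * (end - start + 1)
                    mass_sat = mass_undeut + 1.00628 * n_ex
                    mass_t = mass_undeut + (pct / 100.0) * (mass_sat - mass_undeut)
                    rows.append(
                        {
                            "protein": name,
                            "state": state,
                            "start": start,
                            "end": end,
                            "sequence": seq[start - 1 : end],
                            "timepoint_s": timepoint_s,
                            "mass_t": mass_t,
                            "mass_undeut": mass_undeut,
                            "mass_sat": mass_sat,
                            "percent_d": pct,
                        }
                    )
                if end >= length:
                    break
                start += tiling_step
    peptides = pd.DataFrame(rows)
    # full coverage check (modulo first-residue/proline exclusions)
    for name, seq in sequences.items():
        sub = peptides[peptides["protein"] == name]
        covered = set()
        for r in sub.itertuples():
            covered.update(_covered_sites(r.start, r.end, seq, True, True))
        expected = {
            i
            for i in range(2, length + 1)
            if seq[i - 1] != "P"
        }
        missing = expected - covered
        if missing:
            raise ValueError(
                f"tiling left residues uncovered in {name}: {sorted(missing)[:5]}"
            )
    return peptides, sequences, truth


def simulate_regulons(
    n_genes: int,
    regulon_map: dict,
    effect_by_regulon: dict,
    dispersion: float,
    n_species: int = 2,
    seed: int = 0,
    effect_overrides: dict | None = None,
) -> pd.DataFrame:
    """Regulon-structured log2 fold-change tables for several species.

    Every gene's log2FC is its regulator's programmed effect plus
    Normal(0, dispersion) noise; species share ortholog (gene) identifiers.
    ``effect_overrides`` maps ``species -> {regulator: effect}`` to diverge
    one species' regulon behavior (e.g. a regulon with zero net response).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    genes = sorted(regulon_map)
    if len(genes) != n_genes:
        raise ValueError(f"regulon_map has {len(genes)} genes, expected {n_genes}")
    for g in genes:
        if regulon_map[g] not in effect_by_regulon:
            raise ValueError(f"gene {g!r} maps to unknown regulator {regulon_map[g]!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_species):
        species = f"species{s + 1}"
        effects = dict(effect_by_regulon)
        if effect_overrides and species in effect_overrides:
            effects.update(effect_overrides[species])
        noise = rng.normal(0.0, dispersion, len(genes)) if dispersion > 0 else np.zeros(
            len(genes)
        )
        for g, eps in zip(genes, noise):
            rows.append(
                {
                    "gene": g,
                    "species": species,
                    "regulator": regulon_map[g],
                    "log2fc": effects[regulon_map[g]] + eps,
                }
            )
    return pd.DataFrame(rows)
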