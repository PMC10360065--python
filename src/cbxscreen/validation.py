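"""End-to-end recovery studies on synthetic data.

Each function runs one stage of the pipeline against the generator's
ground truth and reports summary metrics.  They are the package's own
validation experiments: the test suite asserts on their outputs and the
reproduction script re-runs them from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AssayConfig
from .kinetics import fit_one_phase_decay, k2_from_regression
from .labeling import assign_peaks, reversibility_check
from .masses import (
    disulfide_species,
    enumerate_adducts,
    parse_formula,
    peptide_formula,
)
from .simulate import (
    PEPTIDES,
    simulate_kinetics_series,
    simulate_labeling_experiment,
    simulate_stability_suite,
    simulate_treatment,
)
from .stability import stability_result

CBT_CORE_FORMULA = "C8H4N2S"  # 2-cyanobenzothiazole


def recover_k2_regression(true_k2: float, noise_sd: float, seed: int,
                          compound_conc: float = 5e-5,
                          excess_ratios=(10, 15, 20, 30, 40, 50, 70),
                          ) -> float:
    """Recover k2 from seven simulated cysteine concentrations.

    Wells are simulated at ``excess_ratios`` x the compound concentration
    (all pseudo-first-order valid), each decay is fitted at its most
    responsive wavelength, and k2 comes from the k_obs vs [Cys] slope.
    All wells share one read schedule, as on a real plate: ~5 half-lives
    of the median well, 97 reads, dead time 1% of the window — the
    faster, denser assay used for reactive compounds, scaled so one
    routine resolves rate constants spanning orders of magnitude.
    """
    from .stability import most_responsive_wavelength

    cys = [compound_conc * r for r in excess_ratios]
    c_mid = sorted(cys)[len(cys) // 2]
    duration = 5.0 / (true_k2 * c_mid)
    cfg = AssayConfig(dead_time=max(1.0, duration / 100), duration=duration)
    tt = np.linspace(cfg.dead_time, duration, 97)
    pairs = []
    for i, c in enumerate(cys):
        s = simulate_kinetics_series(true_k2, compound_conc, [c], cfg,
                                     seed=seed + i, noise_sd=noise_sd,
                                     timepoints=tt)[0]
        lam = most_responsive_wavelength(s)
        j = s.wavelength_index(lam)
        fit = fit_one_phase_decay(s.timepoints, s.absorbance[:, j], cfg)
        pairs.append((c, fit.k_obs))
    return k2_from_regression(pairs).k2


def pseudo_first_order_errors(true_k2: float = 10.0,
                              compound_conc: float = 5e-5,
                              excess_ratios=(10, 8, 6, 4, 3, 2),
                              ) -> list[float]:
    """Relative k_obs error of exponential fits to exact second-order traces.

    Returns one relative error per excess ratio (noiseless), against the
    nominal k_obs = k2 x [Cys]0.
    """
    from .stability import most_responsive_wavelength

    errs = []
    for ratio in excess_ratios:
        cys = ratio * compound_conc
        nominal = true_k2 * cys
        duration = 6.0 / nominal
        cfg = AssayConfig(dead_time=0.02 * duration, duration=duration)
        s = simulate_kinetics_series(true_k2, compound_conc, [cys], cfg,
                                     seed=0, mode="second_order",
                                     noise_sd=0.0, allow_low_excess=True)[0]
        lam = most_responsive_wavelength(s)
        j = s.wavelength_index(lam)
        fit = fit_one_phase_decay(s.timepoints, s.absorbance[:, j], cfg)
        errs.append(abs(fit.k_obs - nominal) / nominal)
    return errs


@dataclass(frozen=True)
class StabilityAccuracy:
    class_accuracy: float
    mechanism_accuracy: float
    n_series: int
    n_mechanism: int


def stability_screen_accuracy(n_series: int, noise_sd: float,
                              seed: int) -> StabilityAccuracy:
    """Classification and mechanism accuracy on the labeled suite.

    Mechanism discrimination (degradation vs plate binding) is scored on
    the unstable series, where the diagnosis is defined.
    """
    suite = simulate_stability_suite(n_series, noise_sd=noise_sd, seed=seed)
    ok_cls = ok_mech = n_mech = 0
    for e in suite:
        r = stability_result(e.series)
        ok_cls += (r.stability_class == e.true_class)
        if e.true_class == "unstable":
            n_mech += 1
            ok_mech += (r.mechanism == e.truth.scenario)
    return StabilityAccuracy(
        class_accuracy=ok_cls / n_series,
        mechanism_accuracy=ok_mech / max(n_mech, 1),
        n_series=n_series, n_mechanism=n_mech)


@dataclass(frozen=True)
class LabelingRoundTrip:
    max_conversion_error_pct: float
    peak_assignment_accuracy: float
    nh3_loss_assigned_without_ncys: int
    thioimidate_persist_after_cys: int
    species_changed_after_dtt: int
    n_compounds: int


def labeling_round_trip(seed: int, n_compounds: int = 20,
                        area_noise_rel: float = 0.0) -> LabelingRoundTrip:
    """Simulate a labeling cohort, re-analyze it, compare to ground truth.

    The cohort spans k2 from 0.1 to 100 s^-1 M^-1 against both model
    peptides; assignments are checked peak-by-peak against the generator's
    species, and the Cys/DTT treatments are verified to remove exactly the
    reversible thioimidate species / nothing.
    """
    k2s = np.logspace(-1, 2, n_compounds)
    compounds = {f"c{i + 1}": float(k) for i, k in enumerate(k2s)}
    formulas = {cid: CBT_CORE_FORMULA for cid in compounds}
    max_err = 0.0
    n_peaks = n_correct = 0
    bad_nh3 = 0
    thio_persist = dtt_changed = 0
    for pep_id in ("UP1", "UP2"):
        seq, has_cys = PEPTIDES[pep_id]
        pf = peptide_formula(seq)
        cf = parse_formula(CBT_CORE_FORMULA)
        sim = simulate_labeling_experiment(
            compounds, pep_id, formulas, seed=seed,
            area_noise_rel=area_noise_rel)
        for cid, (peaks, truth) in sim.items():
            cands = enumerate_adducts(pf, has_cys, cf, 3, peptide_id=pep_id,
                                      compound_id=cid)
            cands.append(disulfide_species(pf, peptide_id=pep_id))
            res = assign_peaks(peaks, cands, blank_area=1000.0)
            max_err = max(max_err, abs(res.conversion_pct
                                       - truth.conversion_pct))
            truth_map = dict(truth.species_by_peak)
            for pid, sp in res.species_assignments.items():
                n_peaks += 1
                key = truth_map[pid]
                if key == (-1, -1):
                    n_correct += bool(getattr(sp, "is_disulfide", False))
                    continue
                ok = sp is not None and not isinstance(sp, str) and \
                    (sp.n_labels, sp.n_thiazoline) == key
                n_correct += ok
                if not has_cys and getattr(sp, "n_thiazoline", 0):
                    bad_nh3 += 1
            if pep_id == "UP1" and truth.k2 > 5.0:
                t_peaks, _ = simulate_treatment(peaks, truth, "Cys",
                                                CBT_CORE_FORMULA)
                after = assign_peaks(t_peaks, cands, blank_area=1000.0)
                rep = reversibility_check(res, after, "Cys")
                thio_persist += len(rep.anomalies)
                d_peaks, _ = simulate_treatment(peaks, truth, "DTT",
                                                CBT_CORE_FORMULA)
                after_d = assign_peaks(d_peaks, cands, blank_area=1000.0)
                rep_d = reversibility_check(res, after_d, "DTT")
                dtt_changed += len(rep_d.anomalies)
    return LabelingRoundTrip(
        max_conversion_error_pct=max_err,
        peak_assignment_accuracy=n_correct / n_peaks,
        nh3_loss_assigned_without_ncys=bad_nh3,
        thioimidate_persist_after_cys=thio_persist,
        species_changed_after_dtt=dtt_changed,
        n_compounds=n_compounds)
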