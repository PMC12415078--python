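"""Calibrate the per-regime noise model against the sucrose repeatability.

For each acquisition regime this script simulates repeated measurements of a
sucrose standard (nu_B = 5.5 GHz, Gamma_B = 0.43 GHz), fits every spectrum,
and tunes the two noise components so the fitted-parameter standard
deviations match the measured repeatability:

    0.2 s : SD(nu_B) ~ 21 MHz, SD(Gamma_B) ~ 51 MHz
    45 s  : SD(nu_B) ~  5 MHz, SD(Gamma_B) ~ 18 MHz

The white CCD noise fraction controls SD(nu_B) (approximately linearly);
the instrumental width jitter supplies the extra SD(Gamma_B) beyond the
white-noise contribution.  The resulting values are frozen in
``mechanospec.synthetic.NOISE_LEVELS``.

Usage:  python scripts/calibrate_noise.py [--n 400] [--seed 0]
"""

import argparse

import numpy as np

from mechanospec import extract_brillouin_parameters, generate_brillouin_spectrum
from mechanospec.synthetic import PhantomConfig, spheroid_profiles

SUCROSE_NU, SUCROSE_GAMMA = 5.5, 0.43
TARGETS = {"0.2s": (21.0, 51.0), "45s": (5.0, 18.0)}


def monte_carlo_sd(ccd_fraction, width_jitter, n, seed, rayleigh=0.40):
    cfg = PhantomConfig(layout="line", n_rows=1, n_cols=1,
                        class_profiles=spheroid_profiles(),
                        noise_level=ccd_fraction, rayleigh_fwhm=rayleigh)
    rng = np.random.default_rng(seed)
    nus, gammas = [], []
    for _ in range(n):
        jitter = rng.normal(0.0, width_jitter) if width_jitter > 0 else 0.0
        spec = generate_brillouin_spectrum(
            SUCROSE_NU, SUCROSE_GAMMA + jitter, cfg, rng)
        spec.metadata["gamma_B_true"] = SUCROSE_GAMMA
        fit = extract_brillouin_parameters(spec, rayleigh_fwhm=rayleigh)
        if fit.valid:
            nus.append(fit.nu_B)
            gammas.append(fit.gamma_B)
    return 1e3 * np.std(nus), 1e3 * np.std(gammas), len(nus)


def calibrate(regime, n, seed):
    sd_nu_target, sd_gamma_target = TARGETS[regime]
    # 1) white noise from SD(nu): the response is linear through the origin
    probe = 0.02
    sd_nu_probe, _, _ = monte_carlo_sd(probe, 0.0, n, seed)
    ccd = probe * sd_nu_target / sd_nu_probe
    sd_nu, sd_gamma_white, _ = monte_carlo_sd(ccd, 0.0, n, seed + 1)
    # 2) width jitter supplies the remaining Gamma variance in quadrature
    jitter = np.sqrt(max(sd_gamma_target ** 2 - sd_gamma_white ** 2, 0.0)) / 1e3
    sd_nu, sd_gamma, n_ok = monte_carlo_sd(ccd, jitter, n, seed + 2)
    return ccd, jitter, sd_nu, sd_gamma, n_ok


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=400)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    for regime in TARGETS:
        ccd, jitter, sd_nu, sd_gamma, n_ok = calibrate(
            regime, args.n, args.seed)
        t_nu, t_ga = TARGETS[regime]
        print(f"{regime}: ccd_fraction={ccd:.4f} width_jitter={jitter:.4f} GHz"
              f"  -> SD(nu)={sd_nu:.1f} MHz (target {t_nu})"
              f"  SD(Gamma)={sd_gamma:.1f} MHz (target {t_ga})"
              f"  [{n_ok} valid fits]")


if __name__ == "__main__":
    main()
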