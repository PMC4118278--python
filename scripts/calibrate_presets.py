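"""Maintenance script: calibrate the preset latent severity scales.

For each condition preset, solves for the shared latent factor scale at
which the generated share of respondents at full health (profile 11111)
matches the preset's published target, given the preset's marginal
level shares (matched exactly by cut-point calibration) and the common
covariate-effect template. The solved values are frozen into
``eqmap.simulate.PRESET_LATENT_SD``; rerun this script only after
changing the covariate mix, the effect template or the marginal targets.

Usage: python scripts/calibrate_presets.py [--n 40000] [--seed 123]
"""

import argparse

import numpy as np
from scipy import optimize

import eqmap.simulate as sim
from eqmap.simulate import generate_cohort, make_preset


def full_health_share(name: str, latent_sd: float, n: int, seed: int) -> float:
    sim.PRESET_LATENT_SD[name] = latent_sd
    df, _ = generate_cohort(make_preset(name, n=n), seed)
    return float(np.mean(df["eq5d"] == 1.0))


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--n", type=int, default=40_000)
    parser.add_argument("--seed", type=int, default=123)
    args = parser.parse_args()

    for name, target in sim.FULL_HEALTH_TARGETS.items():
        share = optimize.brentq(
            lambda s: full_health_share(name, s, args.n, args.seed) - target,
            0.0,
            6.0,
            xtol=0.02,
        )
        achieved = full_health_share(name, round(share, 2), args.n, args.seed)
        print(f'    "{name}": {share:.2f},  # generated share {achieved:.3f}, target {target}')


if __name__ == "__main__":
    main()
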