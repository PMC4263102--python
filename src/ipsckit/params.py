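"""Published group-mean kinetic parameters used as generative inputs.

These are the reference values for GABA-A IPSCs recorded in spinal lamina II
interneurons of GAD65-EGFP mice: biexponential decay parameters of evoked
IPSCs under high-Cl (-70 mV holding) and low-Cl (0 mV holding) conditions,
and the three-component Gaussian decompositions of the miniature-IPSC
decay-constant distributions.  They parameterize the synthetic-data
generators and serve as recovery targets for round-trip analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

from .mixture import MixtureSpec


@dataclass(frozen=True)
class BiexpDecayParams:
    """Mean dual-exponential decay parameters of an evoked IPSC."""

    a1: float   # fast-component amplitude, pA
    tau1: float  # fast time constant, ms
    a2: float   # slow-component amplitude, pA
    tau2: float  # slow time constant, ms

    @property
    def tau_w(self) -> float:
        """Amplitude-weighted decay time constant, ms."""
        return (self.tau1 * self.a1 + self.tau2 * self.a2) / (self.a1 + self.a2)


# Evoked-IPSC decay, high internal Cl-, holding -70 mV
EIPSC_HIGH_CL = {
    "egfp_neg": BiexpDecayParams(31.5, 31.9, 15.1, 152.0),
    "egfp_pos": BiexpDecayParams(24.3, 43.0, 14.3, 277.9),
}

# Evoked-IPSC decay, low internal Cl-, holding 0 mV
EIPSC_LOW_CL = {
    "egfp_neg": BiexpDecayParams(45.4, 35.0, 16.4, 161.0),
    "egfp_pos": BiexpDecayParams(22.6, 45.5, 14.3, 398.2),
}

# Calibration targets for the Markov scheme: mean fast (tau1) and slow (tau2)
# decay components across the two cell populations, high-Cl recordings.
FAST_DECAY_TARGET_MS = (EIPSC_HIGH_CL["egfp_neg"].tau1 + EIPSC_HIGH_CL["egfp_pos"].tau1) / 2.0   # 37.45
SLOW_DECAY_TARGET_MS = (EIPSC_HIGH_CL["egfp_neg"].tau2 + EIPSC_HIGH_CL["egfp_pos"].tau2) / 2.0   # 214.95

# Three-component Gaussian decompositions of mIPSC decay-constant
# distributions (weight, mean ms, SD ms), per cell population.
MIXTURE_EGFP_NEG = MixtureSpec(
    weights=(0.34, 0.46, 0.20),
    means=(26.6, 69.8, 183.8),
    sds=(9.5, 32.4, 89.7),
)
MIXTURE_EGFP_POS = MixtureSpec(
    weights=(0.23, 0.38, 0.39),
    means=(26.4, 66.1, 249.0),
    sds=(3.9, 35.3, 57.9),
)

# Kinetics of the recorded fast miniature IPSC used as the synaptic drive in
# the dendritic-filtering simulation.
FILTER_INPUT_DECAY_TAU_MS = 27.3
FILTER_INPUT_RISE_10_90_MS = 1.2

# Fast/slow category boundary for the charge-transfer analysis (interface
# between the second and third Gaussian components).
FAST_SLOW_CUTOFF_MS = 100.0
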