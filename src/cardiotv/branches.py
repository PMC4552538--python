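"""Branch metadata for the two MISO models of autonomic control.

The heart-rate variability (HRV) model explains R-R interval fluctuations
through two branches: the arterial baroreflex (ABR, systolic pressure ->
R-R interval) and respiratory-cardiac coupling (RCC, tidal volume ->
R-R interval).  The peripheral-resistance model explains normalized PAT
amplitude fluctuations through baroreflex control of peripheral vascular
conductance (BPC, mean arterial pressure -> PATampN) and
respiratory-peripheral coupling (RPC, tidal volume -> PATampN).

Each branch carries an admissible latency range (seconds) used to impose
causality when untangling the closed cardiovascular loop, and admissible
grids for the Meixner basis expansion (order of generalization and number of
basis functions).
"""

from __future__ import annotations

from dataclasses import dataclass

# Kernel memory: 50 lags at 0.5 s sampling, i.e. 25 s of history.
MEMORY = 50
DT = 0.5
FS = 2.0


@dataclass(frozen=True)
class BranchSpec:
    name: str
    input_name: str
    output_name: str
    delay_range_s: tuple[float, float]
    gen_order_range: tuple[int, int]
    n_funcs_range: tuple[int, int]
    gain_units: str


BRANCHES: dict[str, BranchSpec] = {
    "ABR": BranchSpec("ABR", "dSBP", "dRRI", (0.5, 3.0), (1, 5), (3, 6), "ms/mmHg"),
    "RCC": BranchSpec("RCC", "dVT", "dRRI", (-3.0, 0.0), (0, 5), (3, 6), "ms/L"),
    "BPC": BranchSpec("BPC", "dMAP", "dPATampN", (3.5, 8.0), (2, 8), (2, 6), "1/mmHg"),
    "RPC": BranchSpec("RPC", "dVT", "dPATampN", (0.0, 3.0), (2, 8), (2, 6), "1/L"),
}

# The two models, each a pair of branches feeding one output.
MODELS: dict[str, tuple[str, str]] = {
    "hrv": ("ABR", "RCC"),
    "pr": ("BPC", "RPC"),
}


def check_delay(branch: str, delay_s: float) -> None:
    lo, hi = BRANCHES[branch].delay_range_s
    if not (lo <= delay_s <= hi):
        raise ValueError(
            f"{branch} delay {delay_s:g} s outside admissible range [{lo:g}, {hi:g}] s"
        )
    if abs(delay_s / DT - round(delay_s / DT)) > 1e-9:
        raise ValueError(f"{branch} delay {delay_s:g} s is not on the {DT:g} s grid")


def delay_to_samples(delay_s: float) -> int:
    return int(round(delay_s / DT))
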