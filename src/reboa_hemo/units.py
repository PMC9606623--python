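"""Unit conversions between clinical and SI quantities.

Clinical units (mmHg, L/min, bpm) appear only at the configuration and
reporting surface; everything internal is SI (Pa, m3/s, s).
"""

MMHG_PER_PA = 1.0 / 133.322
PA_PER_MMHG = 133.322
M3S_PER_LMIN = 1.0 / 60000.0
LMIN_PER_M3S = 60000.0


def mmhg_to_pa(p_mmhg):
    return p_mmhg * PA_PER_MMHG


def pa_to_mmhg(p_pa):
    return p_pa * MMHG_PER_PA


def lmin_to_m3s(q_lmin):
    return q_lmin * M3S_PER_LMIN


def m3s_to_lmin(q_m3s):
    return q_m3s * LMIN_PER_M3S


def bpm_to_period_s(hr_bpm: float) -> float:
    if hr_bpm <= 0:
        raise ValueError(f"heart rate must be positive, got {hr_bpm}")
    return 60.0 / hr_bpm
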