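"""Reference cohort configurations.

Group means and SDs (n = 6 per group) for the two simulated rat strains
the pipeline is built to compare: Zucker lean (ZL) controls and Zucker
diabetic fatty (ZDF fa/fa) rats, a type-2-diabetes model with early
diastolic dysfunction at preserved ejection fraction.  These values are
the generator's stated world; cohort simulations draw subjects from them.
"""

from .cohort import CohortSpec

__all__ = ["ZL_CONTROL", "ZDF", "ZL_LVEF", "ZDF_LVEF", "zl_mean_spec"]

#: group mean +- SD of LV ejection fraction (%), not an independent curve
#: parameter (EF follows from EDV and ESV) but used as a recovery truth
ZL_LVEF = (62.5, 4.2)
ZDF_LVEF = (59.4, 4.5)

#: Zucker lean control group: normal systolic and diastolic function.
ZL_CONTROL = CohortSpec(
    edv=(410.8, 60.3),      # µL
    esv=(155.1, 31.4),      # µL
    hr=(331.0, 35.0),       # bpm
    pfr=(12.1, 0.8),        # EDV/s
    third_mfr=(12.0, 0.7),  # EDV/s
    tpfr=(35.4, 2.7),       # ms
    n_subjects=6,
    name="ZL",
)

#: Zucker diabetic fatty group: reduced filling rates, prolonged TPFR,
#: preserved EF and HR.
ZDF = CohortSpec(
    edv=(478.8, 77.9),
    esv=(194.1, 36.6),
    hr=(309.0, 24.0),
    pfr=(10.2, 1.0),
    third_mfr=(9.9, 1.2),
    tpfr=(40.0, 4.2),
    n_subjects=6,
    name="ZDF",
)


def zl_mean_spec(with_third_mfr: bool = False, n_harmonics: int = 6):
    """CurveSpec at the ZL group means (the standard recovery truth).

    1/3MFR is excluded by default: at the ZL means it sits within 1% of
    PFR, which no band-limited curve with a true end-systolic minimum can
    realize (see phantom.synthesis module docstring).
    """
    from .synthesis import CurveSpec

    return CurveSpec(
        edv=ZL_CONTROL.edv[0], esv=ZL_CONTROL.esv[0],
        heart_rate=ZL_CONTROL.hr[0], pfr=ZL_CONTROL.pfr[0],
        tpfr=ZL_CONTROL.tpfr[0],
        third_mfr=ZL_CONTROL.third_mfr[0] if with_third_mfr else None,
        n_harmonics=n_harmonics,
    )
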