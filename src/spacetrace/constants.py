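"""Physical constants shared across the package.

The mass defect of a single ``12C -> 13C`` substitution and the natural
abundance of 13C are the only two physical constants the pipeline relies on.
Both are configurable wherever they are used; these are the defaults.
"""

#: Mass difference between 13C and 12C in daltons.
DELTA_C13: float = 1.003355

#: Natural abundance of 13C (fraction of carbon atoms).
P_C13: float = 0.0107

#: Recognized tracer codes. ``none`` marks an unlabeled (control) section.
TRACERS = ("none", "glc13", "gln13", "lin13")

#: Timepoints (minutes) at which labeled sections are acquired, per tracer.
#: Uniformly labeled glucose and glutamine follow the 5-point design; the
#: linoleate tracer uses the sparser 3-point design.
DEFAULT_TIMEPOINTS = {
    "glc13": (0.0, 15.0, 30.0, 60.0, 120.0),
    "gln13": (0.0, 15.0, 30.0, 60.0, 120.0),
    "lin13": (0.0, 60.0, 120.0),
}
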