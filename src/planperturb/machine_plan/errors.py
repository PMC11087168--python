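"""Error taxonomy for plan I/O and validation."""


class PlanError(Exception):
    """Base class for plan-level errors."""


class UnsupportedPlanError(PlanError):
    """The file lacks the MLC leaf-sequence data this toolkit requires."""


class UnsupportedMachineError(PlanError):
    """The plan was made for a machine other than a 120-leaf MLC."""


class MalformedPlanError(PlanError):
    """Structurally broken plan data (e.g. non-monotone cumulative meterset)."""


class PlanValidationError(PlanError):
    """A plan failed invariant validation prior to writing."""
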