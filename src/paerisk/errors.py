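"""Exception hierarchy for the risk pipeline."""


class PaeriskError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PaeriskError, ValueError):
    """A measured quantity is out of its physical domain (e.g. c < 0)."""


class InvalidFactorsError(PaeriskError, ValueError):
    """An exposure-factor block is unusable (non-positive IR/BW/AT, ...)."""


class InvalidToxicityError(PaeriskError, ValueError):
    """A toxicity profile is unusable (non-positive RfC, negative SF, ...)."""


class MissingSlopeFactorError(PaeriskError, LookupError):
    """A cancer-risk quantity was requested for a non-carcinogen."""


class ConfigurationError(PaeriskError, ValueError):
    """Pipeline configuration is inconsistent or incomplete."""


class GenerationError(PaeriskError, RuntimeError):
    """The synthetic-data generator could not produce a valid table."""


class FixtureError(PaeriskError, RuntimeError):
    """Exact moment matching failed on a degenerate generated sample."""


class SamplingError(PaeriskError, RuntimeError):
    """A Monte-Carlo distribution could not be sampled (empty support, ...)."""
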