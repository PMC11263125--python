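"""Typed exceptions raised across the package.

Every validation failure maps to one of these; nothing is silently dropped.
"""


class CopruneError(Exception):
    """Base class for all package errors."""


class FormatError(CopruneError):
    """A file does not conform to the expected tabular schema."""


class ConsistencyError(CopruneError):
    """Cross-referential integrity violated (unknown species/site, an
    interaction recorded at a site where a partner is absent, mismatched
    site lists, or a network that is not a subset of its co-occurrence
    network)."""


class DegenerateInputError(CopruneError):
    """Input is structurally valid but the requested quantity is undefined
    on it (empty degree sample, zero co-occurrence links, too few points
    for a correlation)."""


class FitDegenerateError(DegenerateInputError):
    """A degree sample lacks the variation needed to identify the family's
    parameters (e.g. a single distinct value for a two-parameter family)."""


class OptimizationError(CopruneError):
    """A maximum-likelihood optimization failed to converge; carries the
    optimizer diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class InfeasibleTargetError(CopruneError):
    """A calibration target cannot be reached for structural reasons (the
    conditional expectation is bounded below by the number of consumers and
    above by the number of co-occurrence links)."""
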