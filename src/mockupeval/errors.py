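"""Exception hierarchy shared across the package."""


class MockupEvalError(Exception):
    """Base class for all package errors."""


class FormatError(MockupEvalError):
    """A file could not be parsed in the documented dialect."""


class ValidationError(MockupEvalError):
    """Parsed data violates a documented invariant.

    ``failures`` lists every violated invariant, not only the first.
    """

    def __init__(self, failures):
        if isinstance(failures, str):
            failures = [failures]
        self.failures = list(failures)
        super().__init__("; ".join(self.failures))


class ReachabilityError(MockupEvalError):
    """No obstacle-free path exists between the requested endpoints."""


class SimulationError(MockupEvalError):
    """A scenario script cannot be executed on the given layout."""
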