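"""Exception types raised by repgwas."""


class RepgwasError(Exception):
    """Base class for repgwas errors."""


class DataError(RepgwasError, ValueError):
    """Invalid or inconsistent input data (bad dosage codes, id mismatches...)."""


class EmptyGenotypeError(DataError):
    """A genotype source yielded zero usable sites or individuals."""


class ConvergenceError(RepgwasError, RuntimeError):
    """Variance-component estimation failed to converge.

    Carries the optimizer trace in ``trace`` for post-mortem inspection.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
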