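"""Exception types raised across the toolkit."""


class IpscKitError(Exception):
    """Base class for all toolkit errors."""


class IntegrationError(IpscKitError):
    """Macroscopic ODE integration produced a non-finite solution."""


class CalibrationError(IpscKitError):
    """Rate-constant calibration could not bracket or reach the target."""


class FitConvergenceError(IpscKitError):
    """A least-squares fit failed to converge; diagnostics in args."""
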