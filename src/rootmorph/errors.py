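"""Package-specific exceptions."""


class RootmorphError(Exception):
    """Base class for all package errors."""


class DivisionRetry(RootmorphError):
    """The proposed division line is degenerate (hits a vertex or the cell is
    too non-convex for a two-edge cut); the caller should redraw the angle."""


class NoPositiveEquilibrium(RootmorphError):
    """The activator-inhibitor kinetics admit no positive homogeneous
    equilibrium (beta*gamma - (alpha_s - alpha_d)*delta <= 0)."""


class DegenerateGeometry(RootmorphError):
    """A zero-length wall or zero-area cell makes a force or division
    computation ill-defined."""


class CohortSchemaError(RootmorphError):
    """A cohort table violates the documented CSV schema."""
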