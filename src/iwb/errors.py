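"""Exception types shared across the package."""


class IWBError(Exception):
    """Base class for all package errors."""


class InvalidScenarioError(IWBError, ValueError):
    """A scenario, parameter set or configuration violates an invariant."""


class InvalidAllocationError(IWBError, ValueError):
    """An allocation is negative or violates the budget constraint."""


class BoundaryError(IWBError, ValueError):
    """A quantity is undefined at the requested boundary point."""
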