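"""Exception hierarchy shared by all confens modules."""


class ConfensError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ConfensError):
    """A structure file could not be parsed."""


class StructuralError(ConfensError):
    """Ensembles or frames are structurally inconsistent (atom counts, topologies)."""


class SelectionError(ConfensError):
    """An atom/residue selection matched nothing or referenced missing atoms."""


class InputError(ConfensError, ValueError):
    """Invalid argument values (non-positive lengths, bad weights, ...)."""


class CriterionError(ConfensError):
    """A geometric interaction criterion cannot be evaluated on this topology."""
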