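"""Exception hierarchy."""


class SeedkitError(Exception):
    """Base class for all seedkit errors."""


class InputError(SeedkitError):
    """Bad user input: missing file, unknown metabolite id, invalid config."""


class FormatError(SeedkitError):
    """Structurally invalid model: missing bounds, non-positive stoichiometry."""


class SearchRefused(SeedkitError):
    """A solver refused an input outside its intended size envelope."""


class ContractViolation(SeedkitError):
    """An operation was called with arguments violating its precondition."""
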