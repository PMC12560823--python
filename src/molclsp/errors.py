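"""Exception taxonomy: bad user data vs bad configuration."""


class InputError(ValueError):
    """The supplied data (file, molecule, index set) is unusable."""


class ConfigurationError(ValueError):
    """A parameter or option is out of its legal range or missing."""
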