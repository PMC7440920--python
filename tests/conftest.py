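"""Shared pytest configuration."""

from hypothesis import HealthCheck, settings

# deterministic, CI-friendly hypothesis defaults
settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")
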