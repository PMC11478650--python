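import pytest

from larvacount import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def make_scene():
    """Session-wide scene factory with caching.

    Several test modules exercise the same study-condition scenes; configs
    are frozen dataclasses, so they key a cache directly and each scene is
    rendered at most once per session.
    """
    cache = {}

    def _make(config: SceneConfig):
        if config not in cache:
            cache[config] = generate_scene(config)
        return cache[config]

    return _make
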