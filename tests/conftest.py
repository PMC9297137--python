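import numpy as np
import pytest

from foodtract.lexicon import FoodEntry, FoodLexicon


@pytest.fixture
def tiny_lexicon() -> FoodLexicon:
    """Handful of entries exercising multi-word and missing-nutrient cases."""
    return FoodLexicon(
        [
            FoodEntry("apple", "healthy", {"calories": 52, "cholesterol": 0, "potassium": 107}),
            FoodEntry("kale", "healthy", {"calories": 49, "potassium": 491}),
            FoodEntry("burger", "unhealthy", {"calories": 250, "cholesterol": 55}),
            FoodEntry("cake", "unhealthy", {"calories": 350, "cholesterol": 55}),
            FoodEntry("red velvet cake", "unhealthy", {"calories": 367, "cholesterol": 52}),
            FoodEntry("burger king", "fastfood", {}),
        ]
    )


@pytest.fixture
def senti_lexicon() -> dict[str, int]:
    return {"love": 1, "great": 1, "delicious": 1, "hate": -1, "gross": -1}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
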