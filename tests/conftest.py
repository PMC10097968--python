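import json

import pytest

from foodtiers import Evaluator, load_default_matrix
from foodtiers.lexicon import Lexicon
from foodtiers.product_model import Product, ReferenceRegistry
from foodtiers.synthetic import all_pass_template


@pytest.fixture(scope="session")
def lexicon():
    return Lexicon.load_default()


@pytest.fixture(scope="session")
def matrix():
    return load_default_matrix()


@pytest.fixture(scope="session")
def references():
    return ReferenceRegistry.default()


@pytest.fixture(scope="session")
def evaluator(matrix, lexicon, references):
    return Evaluator(matrix=matrix, lexicon=lexicon, references=references)


@pytest.fixture()
def dairy_doc():
    return all_pass_template("dairy")


@pytest.fixture()
def dairy_ctx(evaluator, dairy_doc):
    ctx, _, _ = evaluator.prepare(Product.model_validate(dairy_doc))
    return ctx


def as_product(doc: dict) -> Product:
    return Product.model_validate(json.loads(json.dumps(doc)))
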