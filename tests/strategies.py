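"""Hypothesis strategies shared across the suite."""

from hypothesis import strategies as st

from roughnet.core import AttributeSchema, DECISION, build_information_system


@st.composite
def small_tables(draw, min_objects=2, max_objects=12, min_attrs=1, max_attrs=6,
                 cardinality=3, n_classes=2):
    """Random categorical information systems, small enough for brute force."""
    n_obj = draw(st.integers(min_objects, max_objects))
    n_attr = draw(st.integers(min_attrs, max_attrs))
    rows = [
        [f"v{draw(st.integers(0, cardinality - 1))}" for _ in range(n_attr)]
        for _ in range(n_obj)
    ]
    decisions = [f"c{draw(st.integers(0, n_classes - 1))}" for _ in range(n_obj)]
    attrs = [AttributeSchema(name=f"a{j + 1}") for j in range(n_attr)]
    decision = AttributeSchema(name="class", role=DECISION)
    return build_information_system(rows, attrs, decision, decisions)
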