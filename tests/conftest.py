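import textwrap

import pytest

from modelevo.model_io import parse_model

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
CELLML_NS = "http://www.cellml.org/cellml/1.0#"

# hand-built fixture: 15 elements; 2 species, 1 reaction, 1 compartment,
# 1 parameter (counts verified by the enumeration oracle in the tests)
SBML_SMALL = textwrap.dedent(f"""\
    <sbml xmlns="{SBML_NS}" level="2" version="4">
      <model id="m1">
        <listOfCompartments>
          <compartment id="c1" size="1"/>
        </listOfCompartments>
        <listOfSpecies>
          <species id="s1" compartment="c1" initialConcentration="1"/>
          <species id="s2" compartment="c1" initialConcentration="2"/>
        </listOfSpecies>
        <listOfParameters>
          <parameter id="p1" value="0.1"/>
        </listOfParameters>
        <listOfReactions>
          <reaction id="r1">
            <listOfReactants>
              <speciesReference species="s1"/>
            </listOfReactants>
            <listOfProducts>
              <speciesReference species="s2"/>
            </listOfProducts>
          </reaction>
        </listOfReactions>
      </model>
    </sbml>
    """)

# 2 components holding 3 variables, 1 units definition
CELLML_SMALL = textwrap.dedent(f"""\
    <model xmlns="{CELLML_NS}" name="cm1">
      <units name="ms">
        <unit units="second" prefix="milli"/>
      </units>
      <component name="A">
        <variable name="x" units="ms"/>
        <variable name="y" units="ms"/>
      </component>
      <component name="B">
        <variable name="z" units="ms"/>
      </component>
    </model>
    """)


@pytest.fixture
def sbml_small():
    return parse_model(SBML_SMALL, model_id="m1", version_id="v1")


@pytest.fixture
def cellml_small():
    return parse_model(CELLML_SMALL, model_id="cm1", version_id="v1")


@pytest.fixture
def sbml_small_text():
    return SBML_SMALL


@pytest.fixture
def cellml_small_text():
    return CELLML_SMALL
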