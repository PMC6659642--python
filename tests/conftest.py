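import pytest

from gwascurate import load_builtin_dictionary, parse_document
from gwascurate.synthcorpus import CorpusConfig, generate_corpus


@pytest.fixture(scope="session")
def dictionary():
    return load_builtin_dictionary()


@pytest.fixture(scope="session")
def clean_corpus():
    """10 distractor-free synthetic papers with ground truth."""
    cfg = CorpusConfig(n_papers=10, distractor_rate=0.0, seed=7)
    papers, gt = generate_corpus(cfg)
    return papers, gt


@pytest.fixture(scope="session")
def clean_docs(clean_corpus):
    papers, gt = clean_corpus
    docs = [parse_document(xml) for xml in papers.values()]
    return docs, gt


TABLE_XML = b"""<article id="doc1">
 <front><article-meta>
  <article-id pub-id-type="pmid">12345</article-id>
  <title-group><article-title>A study of platelet aggregation</article-title></title-group>
  <abstract><p>We studied platelet aggregation and body mass index (BMI).</p></abstract>
 </article-meta></front>
 <body>
  <p>Results are shown below.</p>
  <table-wrap><table>
   <thead><tr><th>SNP</th><th>Trait</th><th>P value</th></tr></thead>
   <tbody>
    <tr><td>rs17661538</td><td>Clozapine\xe2\x80\x94Triglycerides</td><td>1.00E\xe2\x88\x9206</td></tr>
    <tr><td>rs12566888</td><td>Platelet aggregation</td><td>5.00E\xe2\x88\x9219</td></tr>
    <tr><td>rs13130255</td><td>funcPS</td><td>3.00E\xe2\x88\x9206</td></tr>
   </tbody>
  </table></table-wrap>
 </body>
</article>"""


@pytest.fixture()
def worked_example_doc():
    """A paper shaped like a real association table with three variants."""
    return parse_document(TABLE_XML)
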