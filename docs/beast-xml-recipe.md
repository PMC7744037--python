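# Mapping a model config onto BEAST XML

`mmphylo` deliberately does not read or write BEAST XML. For users who
want to re-express a model from a `mmphylo` YAML/JSON config in a BEAST
analysis (e.g. to add tree-topology sampling or relaxed clocks, which are
out of scope here), the correspondence is:

| mmphylo config field            | BEAST XML concept                          |
|---------------------------------|--------------------------------------------|
| `components[k].sym_rates`       | per-component `gtrModel`/`hkyModel` relative rates |
| `components[k].frequencies`     | `frequencyModel/frequencies` of component k |
| `switching.rates`, `structure`  | the switching CTMC among substitution models (general, possibly non-reversible rate matrix over model categories) |
| `multipliers`                   | per-component rate multipliers (fix to 1 when a site model with gamma categories is present) |
| `asrv.alpha`, `n_categories`    | `siteModel/gammaShape` with the given category count |
| `normalize_rates`               | whether branch lengths count expected substitutions (BEAST normalizes its substitution models analogously) |
| compound model as a whole       | a Markov-modulated substitution model block over the Kronecker-structured compound state space |

Caveats when translating:

- `mmphylo` fixes topology and branch lengths; a BEAST analysis will
  usually estimate both, so marginal likelihoods are not comparable
  between the two without fixing the tree in BEAST as well.
- Priors differ: `mmphylo` defaults are Dirichlet(1) frequencies,
  Gamma(0.5, 1) switching/GTR rates, Lognormal(0, 1) kappa, and an
  Exponential mean-3 gamma shape. Match them explicitly in the XML if
  results are to be compared.
- The root distribution here is the exact stationary distribution of the
  compound generator; verify which convention the target XML uses.
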