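taxon	ST-like	Aquatic
Amoebozoa	absent	present
Fungi	absent	absent
Ichthyosporea	absent	present
Choanoflagellata	absent	absent
Ctenophora	absent	present
Porifera	absent	absent
Placozoa	absent	absent
Anthozoa	present	absent
Staurozoa	absent	absent
Scyphozoa	absent	absent
Cubozoa	absent	absent
Hydrozoa	absent	present
Echinodermata	absent	absent
Hemichordata	absent	absent
Chordata	absent	absent
Rotifera	absent	present
Platyhelminthes	absent	present
Annelida	absent	absent
Mollusca	absent	present
Brachiopoda	absent	present
Nematoda	absent	absent
Priapulida	absent	absent
Tardigrada	absent	absent
Onychophora	absent	absent
Chelicerata	present	absent
Myriapoda	present	absent
Copepoda	absent	absent
Malacostraca	absent	present
Branchiopoda	absent	present
Collembola	absent	present
Insecta	absent	absent
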