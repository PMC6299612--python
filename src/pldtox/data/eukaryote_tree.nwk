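(Amoebozoa,(Fungi,(Ichthyosporea,(Choanoflagellata,(Ctenophora,(Porifera,(Placozoa,((Anthozoa,(Staurozoa,(Scyphozoa,(Cubozoa,Hydrozoa))))C,(((Echinodermata,Hemichordata),Chordata)D,(((Rotifera,Platyhelminthes),(Annelida,(Mollusca,Brachiopoda)))S,(Nematoda,(Priapulida,(Tardigrada,(Onychophora,(Chelicerata,(Myriapoda,(Copepoda,(Malacostraca,(Branchiopoda,(Collembola,Insecta)H)))))A))))E)P)))))M))));
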