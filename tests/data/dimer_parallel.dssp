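==== Secondary Structure Definition; reference asset for the ideal parallel dimer fixture ====
REFERENCE: idealized Crick coiled-coil, 2 chains x 28 residues
  56  2  0  0  0 TOTAL NUMBER OF RESIDUES, NUMBER OF CHAINS, NUMBER OF SS-BRIDGES(TOTAL,INTRACHAIN,INTERCHAIN)
  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA
    1    1 A A    
    2    2 A A  H 
    3    3 A A  H 
    4    4 A A  H 
    5    5 A A  H 
    6    6 A A  H 
    7    7 A A  H 
    8    8 A A  H 
    9    9 A A  H 
   10   10 A A  H 
   11   11 A A  H 
   12   12 A A  H 
   13   13 A A  H 
   14   14 A A  H 
   15   15 A A  H 
   16   16 A A  H 
   17   17 A A  H 
   18   18 A A  H 
   19   19 A A  H 
   20   20 A A  H 
   21   21 A A  H 
   22   22 A A  H 
   23   23 A A  H 
   24   24 A A  H 
   25   25 A A  H 
   26   26 A A  H 
   27   27 A A  H 
   28   28 A A    
   29        !*             0   0    0      0, 0.0     0, 0.0     0, 0.0     0, 0.0   0.000 360.0 360.0 360.0 360.0    0.0    0.0    0.0
   30    1 B A    
   31    2 B A  H 
   32    3 B A  H 
   33    4 B A  H 
   34    5 B A  H 
   35    6 B A  H 
   36    7 B A  H 
   37    8 B A  H 
   38    9 B A  H 
   39   10 B A  H 
   40   11 B A  H 
   41   12 B A  H 
   42   13 B A  H 
   43   14 B A  H 
   44   15 B A  H 
   45   16 B A  H 
   46   17 B A  H 
   47   18 B A  H 
   48   19 B A  H 
   49   20 B A  H 
   50   21 B A  H 
   51   22 B A  H 
   52   23 B A  H 
   53   24 B A  H 
   54   25 B A  H 
   55   26 B A  H 
   56   27 B A  H 
   57   28 B A    
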