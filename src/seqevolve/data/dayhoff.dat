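# DAYHOFF amino-acid exchangeabilities (lower triangle) and stationary frequencies
# state order: A R N D C Q E G H I L K M F P S T W Y V
         27
         98         120
         36          89         198
        240          23          65          41
         26          72          18         250         409
        371           0          24         208          32           0
         23         246           1           9         240          64          15
        464          90          14         103         154          26         201           8
         24         905           0         103         148         139         535          77          34
        318           1          14          42         495         229          23          95          15           0
        134        1153         125          86          24           0          71           0           0          13          95
         66           0           0          18           0           0          11          28          44           0           0           0
          0          19         161          16           0          96          49         716          28         606          18          73         153
        114           0         153          56          53           0           0          35          81          43          61          11          83          30
          0          51          79          34           0          22          37          10           0           7          27          17          15          34         234
         30           0           0          54           7          44          26           0          48          94          35          22          27         127          44         257
         46         336         196          12          24         192           0          37         889          18         527         157          32          17          33          46          28
        175         243           0          33          96         136           0          13          10          92          17          62         104           0           0         258          11          46
         13          76         698          12         245          78           0           0          48         550          75          34          30           0          42         157          61           0          28

0.08712691287 0.0409039591 0.04043195957 0.04687195313 0.03347396653 0.03825496175 0.04952995047 0.08861191139 0.03361796638 0.03688596311 0.08535691464 0.08048191952 0.01475298525 0.03977196023 0.05067994932 0.06957693042 0.05854194146 0.01049398951 0.02991597008 0.06471793528
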