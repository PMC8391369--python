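<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="habits" description="hábitos diarios que el paciente solía realizar">
    <category role="trigger">
      <pattern>COSTUMBRES</pattern>
      <template><random>
        <li>Me contaron que te gustaba <get name="habito_diario"/>. ¿Es verdad?</li>
        <li>Las costumbres dicen mucho de nosotros. ¿Qué solías hacer todas las mañanas?</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>_ COSTUMBRES</pattern>
      <template><srai>COSTUMBRES</srai></template>
    </category>
    <category role="trigger">
      <pattern>COSTUMBRES _</pattern>
      <template><srai>COSTUMBRES</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ COSTUMBRES _</pattern>
      <template><srai>COSTUMBRES</srai></template>
    </category>
    <category role="trigger">
      <pattern>COSTUMBRE</pattern>
      <template><srai>COSTUMBRES</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ COSTUMBRE</pattern>
      <template><srai>COSTUMBRES</srai></template>
    </category>
    <category role="trigger">
      <pattern>COSTUMBRE _</pattern>
      <template><srai>COSTUMBRES</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ COSTUMBRE _</pattern>
      <template><srai>COSTUMBRES</srai></template>
    </category>
    <category role="trigger">
      <pattern>HÁBITOS</pattern>
      <template><srai>COSTUMBRES</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ HÁBITOS</pattern>
      <template><srai>COSTUMBRES</srai></template>
    </category>
    <category role="trigger">
      <pattern>HÁBITOS _</pattern>
      <template><srai>COSTUMBRES</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ HÁBITOS _</pattern>
      <template><srai>COSTUMBRES</srai></template>
    </category>
    <category role="trigger">
      <pattern>RUTINA</pattern>
      <template><srai>COSTUMBRES</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ RUTINA</pattern>
      <template><srai>COSTUMBRES</srai></template>
    </category>
    <category role="trigger">
      <pattern>RUTINA _</pattern>
      <template><srai>COSTUMBRES</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ RUTINA _</pattern>
      <template><srai>COSTUMBRES</srai></template>
    </category>
    <category>
      <pattern>SÍ</pattern>
      <template><random>
        <li>¡Qué bien! ¿Desde cuándo te gusta <get name="habito_diario"/>?</li>
        <li>¿Qué es lo que más disfrutas de <get name="habito_diario"/>?</li>
      </random></template>
    </category>
    <category>
      <pattern>SI</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SÍ _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SI _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>NO</pattern>
      <template>No pasa nada. ¿Qué costumbre disfrutabas en tus días?</template>
    </category>
    <category role="fallback">
      <pattern>*</pattern>
      <template><random>
        <li>Las rutinas guardan lindos recuerdos. ¿Me platicas de tus costumbres?</li>
        <li>Cada día tiene algo especial. ¿Cómo empezabas tu mañana?</li>
      </random></template>
    </category>
  </topic>
</aiml>
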